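# Packaged default trial design: 4 diet groups x 2 genders x 10 cages x
# 2 animals, endpoint panels at months 3/6/12 (interim subsample of 10
# animals per group and gender), weekly recording for 13 weeks then once
# every 2 weeks until week 53.
design:
  groups: ["control", "conventional 2", "11 % GMO", "33 % GMO"]
  control: "control"
  genders: ["male", "female"]
  cages_per_group_per_gender: 10
  animals_per_cage: 2
  observation_months: [3, 6, 12]
  weekly_weeks: 13
  final_week: 53
  subsample_n: 10
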