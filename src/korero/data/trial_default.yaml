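# Default open-trial simulation parameters. These emulate the uptake
# funnel and worry-score distribution of a two-week open trial of a
# COVID-era youth wellbeing chatbot: 393 registrations of whom ~60.6%
# logged in, ~53.4% of logins in the 13-24 target age range, ~70.9%
# of target-age users female and ~47.2% NZ European, session-start worry
# mean 5.1 (SD 2.6) on the 0-10 item, a mean improvement of 0.8 points
# at outro, ~63.8% of target-age users reaching the outro offer, ~37%
# of those completing the recheck, and ~24.4% returning for a repeat
# session. They are emulation targets for the generator, not findings.
n_registered: 393
p_login: 0.6056
p_target_age: 0.5336
age_target_range: [13, 24]
age_nontarget_range: [25, 49]
gender_mix:
  female: 0.709
  male: 0.250
  other_unspecified: 0.041
ethnicity_mix:
  nz_european: 0.472
  maori: 0.200
  pacific: 0.100
  asian: 0.130
  other_unspecified: 0.098
mu_pre: 5.1
sd_pre: 2.6
effect_delta: 0.8
sd_noise: 1.0
p_reach_outro: 0.638
p_complete_outro: 0.370
p_return: 0.244
seed: 0
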