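# Generating parameters for the named synthetic cohorts.
#
# Values marked "reported" are the published point estimates for the
# corresponding study population; the remaining values are package
# defaults chosen to reproduce the qualitative shapes of the two observed
# CL distributions (bimodal memory-clinic vs. near-zero skewed
# pre-dementia).  Edit here to change a preset everywhere.
dpms:
  n: 840
  tracer_split: 0.5
  params:
    pi_neg: 0.45        # default (not reported)
    pi_int: 0.10        # default (not reported)
    pi_pos: 0.45        # default (not reported)
    mu_neg: 0.42        # reported negative-Gaussian mean, CL
    mu_pos: 92.52       # reported positive-Gaussian mean, CL
    sigma_neg: 7.0      # default, CL
    sigma_pos: 30.0     # default, CL
pnhs:
  n: 1600
  tracer_split: 0.5
  params:
    pi_neg: 0.73        # complement of the two reported proportions
    pi_int: 0.20        # reported intermediate proportion
    pi_pos: 0.07        # reported positive proportion
    mu_neg: 0.0         # default: negative mode anchored at 0 CL
    mu_pos: 92.52       # default: reuse the memory-clinic positive mean
    sigma_neg: 7.0      # default, CL
    sigma_pos: 30.0     # default, CL
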