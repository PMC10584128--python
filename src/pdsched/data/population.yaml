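# Default synthetic levodopa population for virtual Parkinson's-disease
# patients.  Means and variabilities are chosen to be representative of
# published oral levodopa population PK/PD analyses (absorption half-life
# ~25 min, central volume ~11 L, clearance ~0.5 L/min, steep sigmoidal
# concentration-effect with EC50 ~1.4 mg/L) while keeping every simulated
# TRS trajectory inside the [-3, 3] scale.  Inter-individual variability is
# multivariate normal with the listed standard deviations and a few mild
# correlations; draws are clipped to the admissible intervals below and
# EMAX is capped at 3 - BASE.
means:
  ka: 0.028        # 1/min, first-order oral absorption
  BIO: 0.84        # bioavailability
  Q: 0.58          # L/min, inter-compartmental clearance
  V1: 11.0         # L, central volume
  V2: 27.0         # L, peripheral volume
  CL: 0.52         # L/min, elimination clearance
  Rsyn: 0.010      # mg/min, endogenous levodopa synthesis
  kEO: 0.025       # 1/min, effect-compartment equilibration
  BASE: -2.2       # TRS, drug-free baseline
  EMAX: 4.6        # TRS, maximum change from baseline
  EC50: 1.4        # mg/L, concentration at half-maximal effect
  gamma: 4.0       # Hill coefficient
sds:
  ka: 0.005
  BIO: 0.08
  Q: 0.10
  V1: 1.8
  V2: 4.5
  CL: 0.09
  Rsyn: 0.003
  kEO: 0.005
  BASE: 0.30
  EMAX: 0.50
  EC50: 0.25
  gamma: 0.60
correlations:
  - [V1, V2, 0.4]
  - [Q, CL, 0.3]
  - [BASE, EMAX, -0.5]
clip_bounds:
  ka: [0.010, 0.060]
  BIO: [0.50, 1.00]
  Q: [0.20, 1.20]
  V1: [6.0, 20.0]
  V2: [14.0, 45.0]
  CL: [0.20, 1.00]
  Rsyn: [0.0, 0.030]
  kEO: [0.008, 0.060]
  BASE: [-3.0, -1.0]
  EMAX: [2.5, 5.8]
  EC50: [0.60, 3.00]
  gamma: [1.5, 8.0]
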