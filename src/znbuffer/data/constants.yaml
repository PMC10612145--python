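# Bundled reference constants: apparent (conditional) values at pH 7.4,
# -log10 molar unless a kd is given explicitly.
#
# Protein stepwise models are macroscopic apparent dissociation constants,
# tightest step first.  Grouped entries expand to one identical constant per
# site.  For the bacterial proteins the tight pair uses the metal-buffer
# average constant, the intermediate site the moderate estimate, and the
# weakest site the fluorescent-probe competition value.
#
# pka_prime: apparent average thiol pKa from pH titrations of the Zn complex.
# par_transfer_eq: mol Zn transferred per mol protein to 200 uM of the 2:1
# chromogenic probe from 1 uM holo-protein (competition endpoint).

proteins:
  BcrMT1B:
    n_sites: 6
    sites:
      tight: [11.5, 11.5, 11.5]
      moderate: [10.5, 9.80]
      weak: [8.03]
    pka_prime: 4.97
    par_transfer_eq: 0.98
  LlMT:
    n_sites: 9
    sites:
      tight: [11.5, 11.5, 11.5, 11.5]
      moderate: [10.9, 10.0]
      weak: [6.75, 6.75, 6.75]
    weak_release: cooperative
    pka_prime: 4.83
    par_transfer_eq: 2.66
  SpMTA:
    n_sites: 7
    sites:
      tight: [11.5, 11.5, 11.5, 11.2]
      moderate: [10.5, 9.31]
      weak: [8.54]
    pka_prime: 4.94
    par_transfer_eq: 1.22
  XlMT:
    n_sites: 7
    sites:
      tight: [11.2, 11.2, 11.2, 11.2]
      moderate: [10.1, 9.37]
      weak: [7.74]
    pka_prime: 4.73
    par_transfer_eq: 1.27
  MacMT3:
    n_sites: 3
    sites:
      tight: [11.4]
      moderate: [9.9]
      weak: [8.81]
    pka_prime: 4.97
    par_transfer_eq: 1.02
  OsMTI-1B:
    n_sites: 4
    sites:
      tight: [11.7]
      moderate: [10.1]
      weak: [7.76, 7.76]
    pka_prime: 5.04
    par_transfer_eq: 1.93
  Ec-1:
    n_sites: 6
    sites:
      tight: [11.1, 11.1, 11.1]
      moderate: [10.8, 9.58]
      weak: [7.96]
    pka_prime: 4.44
    par_transfer_eq: 0.93
  PflQ2MT:
    n_sites: 3
    sites:
      tight: [14.5, 14.5]
      weak: [10.3]
    pka_prime: 4.75
    par_transfer_eq: 0.08
    notes: >-
      tight constants estimated as the mean of the SmtA and TvMT metal-buffer
      values; the protein's own CD competition changes were within
      experimental error and yielded no direct value
  SmtA:
    n_sites: 4
    sites:
      tight: [14.68, 14.68]
      moderate: [12.9]
      weak: [11.2]
    pka_prime: 4.29
    par_transfer_eq: 0.05
    metal_buffer_pkd_av: 14.68
  TvMT:
    n_sites: 4
    sites:
      tight: [14.3, 14.3]
      moderate: [12.6]
      weak: [10.9]
    pka_prime: 4.19
    par_transfer_eq: 0.04
    metal_buffer_pkd_av: 14.3

chelators:
  ATP: {pkd: 5.1}
  triphosphate: {pkd: 6.9}
  NTA: {pkd: 8.4}
  HEDTA: {kd: 6.6e-13}
  EDTA: {kd: 2.3e-14}
  TPEN: {kd: 6.4e-16}

probes:
  PAR:
    stoichiometry: "2:1"
    kd12: 7.1e-13
    epsilon_492: 71500.0
    path_length_cm: 1.0
  ZnAF-2F:
    stoichiometry: "1:1"
    kd: 5.5e-9
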