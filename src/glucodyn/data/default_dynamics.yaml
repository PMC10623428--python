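# Default group-true glucose-dynamics parameters for the synthetic cohort.
# version: 1
#
# Parameters of G(t) = G0 + A*exp(-alpha*t)*sin(2*pi*t/T + phi) per
# intervention x sex x study week (GTT weeks 0/5/12/18, ITT week 18).
# Units: G0, A in mg/dL; alpha in 1/h; T in h; phi in rad.
#
# These defaults encode the qualitative ordering of the study design —
# diet-fed females on liraglutide end with the highest setpoint and the
# slowest return (lowest alpha, longest T), standard-diet males the
# fastest — and are NOT quantitative estimates from any real cohort.
version: 1
gtt:
  STD:
    F:
      0:  {G0: 100.0, A: 85.0, alpha: 1.30, T: 3.0, phi: 0.15}
      5:  {G0: 100.0, A: 85.0, alpha: 1.30, T: 3.0, phi: 0.15}
      12: {G0: 102.0, A: 86.0, alpha: 1.25, T: 3.1, phi: 0.15}
      18: {G0: 103.0, A: 86.0, alpha: 1.20, T: 3.1, phi: 0.15}
    M:
      0:  {G0: 95.0, A: 82.0, alpha: 1.50, T: 2.6, phi: 0.15}
      5:  {G0: 95.0, A: 82.0, alpha: 1.50, T: 2.6, phi: 0.15}
      12: {G0: 96.0, A: 83.0, alpha: 1.48, T: 2.6, phi: 0.15}
      18: {G0: 97.0, A: 83.0, alpha: 1.45, T: 2.7, phi: 0.15}
  HFHSD:
    F:
      0:  {G0: 100.0, A: 85.0, alpha: 1.30, T: 3.0, phi: 0.15}
      5:  {G0: 112.0, A: 90.0, alpha: 1.00, T: 3.6, phi: 0.15}
      12: {G0: 124.0, A: 95.0, alpha: 0.75, T: 4.4, phi: 0.15}
      18: {G0: 138.0, A: 98.0, alpha: 0.60, T: 5.0, phi: 0.15}
    M:
      0:  {G0: 96.0, A: 82.0, alpha: 1.45, T: 2.7, phi: 0.15}
      5:  {G0: 106.0, A: 88.0, alpha: 1.10, T: 3.3, phi: 0.15}
      12: {G0: 116.0, A: 92.0, alpha: 0.90, T: 3.9, phi: 0.15}
      18: {G0: 126.0, A: 95.0, alpha: 0.75, T: 4.4, phi: 0.15}
  HFHSD+M:
    F:
      0:  {G0: 100.0, A: 85.0, alpha: 1.30, T: 3.0, phi: 0.15}
      5:  {G0: 112.0, A: 90.0, alpha: 1.00, T: 3.6, phi: 0.15}
      12: {G0: 114.0, A: 90.0, alpha: 0.90, T: 4.0, phi: 0.15}
      18: {G0: 118.0, A: 92.0, alpha: 0.85, T: 4.2, phi: 0.15}
    M:
      0:  {G0: 96.0, A: 82.0, alpha: 1.45, T: 2.7, phi: 0.15}
      5:  {G0: 106.0, A: 88.0, alpha: 1.10, T: 3.3, phi: 0.15}
      12: {G0: 110.0, A: 89.0, alpha: 1.00, T: 3.6, phi: 0.15}
      18: {G0: 116.0, A: 91.0, alpha: 0.90, T: 3.9, phi: 0.15}
  HFHSD+L:
    F:
      0:  {G0: 100.0, A: 85.0, alpha: 1.30, T: 3.0, phi: 0.15}
      5:  {G0: 112.0, A: 90.0, alpha: 1.00, T: 3.6, phi: 0.15}
      12: {G0: 128.0, A: 96.0, alpha: 0.60, T: 5.0, phi: 0.15}
      18: {G0: 148.0, A: 100.0, alpha: 0.45, T: 6.0, phi: 0.15}
    M:
      0:  {G0: 96.0, A: 82.0, alpha: 1.45, T: 2.7, phi: 0.15}
      5:  {G0: 106.0, A: 88.0, alpha: 1.10, T: 3.3, phi: 0.15}
      12: {G0: 112.0, A: 90.0, alpha: 0.95, T: 3.8, phi: 0.15}
      18: {G0: 120.0, A: 93.0, alpha: 0.85, T: 4.1, phi: 0.15}
itt:
  STD:
    F:
      18: {G0: 98.0, A: 42.0, alpha: 1.00, T: 3.2, phi: 2.60}
    M:
      18: {G0: 94.0, A: 40.0, alpha: 1.10, T: 3.0, phi: 2.60}
  HFHSD:
    F:
      18: {G0: 118.0, A: 48.0, alpha: 0.70, T: 3.8, phi: 2.60}
    M:
      18: {G0: 110.0, A: 46.0, alpha: 0.80, T: 3.6, phi: 2.60}
  HFHSD+M:
    F:
      18: {G0: 108.0, A: 45.0, alpha: 0.85, T: 3.5, phi: 2.60}
    M:
      18: {G0: 105.0, A: 44.0, alpha: 0.90, T: 3.4, phi: 2.60}
  HFHSD+L:
    F:
      18: {G0: 126.0, A: 50.0, alpha: 0.60, T: 4.2, phi: 2.60}
    M:
      18: {G0: 107.0, A: 45.0, alpha: 0.85, T: 3.5, phi: 2.60}
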