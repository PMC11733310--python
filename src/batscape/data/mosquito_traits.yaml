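# Thermal-performance-curve parameters for the relative mosquito-abundance
# index M(T) = EFD * pEA * MDR / max(mu, mu_floor)^2.
#
# Representative Culex-tarsalis-style values (temperate Culex trait fits):
# unimodal curves with thermal limits near 3-40 C and a composite abundance
# peak in the low-to-mid 20s C. M is relative (unitless), so only the curve
# shapes matter downstream; substitute any trait set with the same structure.
#
# Units: EFD eggs female^-1 day^-1; pEA probability; MDR day^-1;
# mu day^-1 (reciprocal of a quadratic lifespan in days); temperatures C.
traits:
  EFD:
    form: briere
    c: 5.98e-3
    tmin: 5.0
    tmax: 38.9
  pEA:
    form: quadratic
    c: 2.4e-3
    tmin: 3.6
    tmax: 38.7
  MDR:
    form: briere
    c: 3.76e-5
    tmin: 3.4
    tmax: 39.9
  mu:
    form: inverted-quadratic
    c: 4.5e-2
    tmin: -5.8
    tmax: 38.9
mu_floor: 0.01
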