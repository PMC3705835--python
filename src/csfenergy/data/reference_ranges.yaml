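# Reference ranges of the basic CSF examination panel.
# Ranges printed as inclusive; values equal to a limit count as in-range.
# Age brackets for infants are in days, for children/adults in whole years
# (a fractional age belongs to the bracket containing its floor year; ages
# above the oldest bracket reuse the oldest bracket).
version: 1
parameters:
  q_glu:
    units: ""
    ranges:
      - {low: 0.55, high: 0.65}
  lactate_csf:
    units: mmol/L
    ranges:
      - {low: 0.7, high: 2.1}
  leukocytes:
    units: /uL
    ranges:
      - {low: 0.0, high: 4.0}
  beta2m_csf:
    units: mg/L
    ranges:
      - {low: 0.2, high: 2.0}
  it_igg:
    units: "%"
    ranges:
      - {low: 0.0, high: 0.0}
  it_iga:
    units: "%"
    ranges:
      - {low: 0.0, high: 0.0}
  it_igm:
    units: "%"
    ranges:
      - {low: 0.0, high: 0.0}
  tp_csf:
    units: mg/L
    ranges:
      - {age_days: [0, 14], low: 450.0, high: 1090.0}
      - {age_days: [14, 28], low: 510.0, high: 1010.0}
      - {age_days: [28, 91], low: 240.0, high: 650.0}
      - {age_days: [91, 182], low: 230.0, high: 370.0}
      - {age_days: [182, 366], low: 170.0, high: 350.0}
      - {age_years: [1, 10], low: 160.0, high: 310.0}
      - {age_years: [11, 18], low: 160.0, high: 400.0}
      - {age_years: [19, 40], low: 240.0, high: 490.0}
      - {age_years: [41, 50], low: 270.0, high: 600.0}
      - {age_years: [51, 60], low: 290.0, high: 670.0}
      - {age_years: [61, 70], low: 260.0, high: 790.0}
  q_alb:
    units: ""
    scale: 1.0e-3  # table values are x10^-3; applied at load
    ranges:
      - {age_days: [0, 14], low: 5.6, high: 23.2}
      - {age_days: [14, 28], low: 7.6, high: 16.4}
      - {age_days: [28, 91], low: 2.3, high: 10.6}
      - {age_days: [91, 182], low: 2.0, high: 4.8}
      - {age_days: [182, 366], low: 1.4, high: 4.5}
      - {age_years: [1, 10], low: 1.0, high: 4.5}
      - {age_years: [11, 18], low: 1.0, high: 5.0}
      - {age_years: [19, 30], low: 1.7, high: 5.7}
      - {age_years: [31, 40], low: 1.8, high: 6.2}
      - {age_years: [41, 50], low: 2.0, high: 7.2}
      - {age_years: [51, 60], low: 2.1, high: 8.9}
      - {age_years: [61, 70], low: 2.2, high: 9.9}
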