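# Default antenatal supplement scenarios per trimester (the free public
# health-service regimen).  Amounts are mg/day over the tracked nutrient
# panel; nutrients absent from the panel (folic acid) contribute nothing.
# Trimester 1: folic acid only -> zero over the tracked panel.
# Trimesters 2-3: elemental iron 100 mg/day (the RNI 2017 supplementation
# figure) plus vitamin C and a B-complex; the C/B-complex amounts are
# configurable defaults, not published compositions.
1:
  name: "folic acid only"
  provided: {}
2:
  name: "folic acid + iron + B complex + vitamin C"
  provided:
    iron_mg: 100
    vitC_mg: 100
    vitB1_mg: 5
    vitB2_mg: 5
    vitB3_mg: 20
3:
  name: "folic acid + iron + B complex + vitamin C"
  provided:
    iron_mg: 100
    vitC_mg: 100
    vitB1_mg: 5
    vitB2_mg: 5
    vitB3_mg: 20
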