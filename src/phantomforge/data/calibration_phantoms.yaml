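# Ancillary quantitative-SPECT calibration phantoms: design values for
# fill planning. Concise notation: value(standard uncertainty in last digits).
jaszczak:
  description: cylindrical calibration phantom, uniform fill
  nominal_volume_L: 6.9
  activity_MBq: 409(14)
nema_iec_body:
  description: six-sphere body phantom, uniform sphere concentration,
    water-filled background
  stock_concentration_MBq_per_mL: 2.00(6)
  sphere_volumes_mL:
    - 0.53(2)
    - 1.17(2)
    - 2.54(2)
    - 5.58(2)
    - 11.59(2)
    - 26.7(2)
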