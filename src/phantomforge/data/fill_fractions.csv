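compartment,stl_volume_mL,scan,fill_fraction_pct
liver,1306.7,1,100.08(1)
liver,1306.7,2,99.84(1)
liver,1306.7,3,100.04(1)
liver,1306.7,4,99.95(1)
liver,1306.7,5,100.13(1)
liver,1306.7,6,99.89(1)
spleen,124.9,1,99.43(2)
spleen,124.9,2,99.45(2)
spleen,124.9,3,99.40(2)
spleen,124.9,4,99.21(2)
spleen,124.9,5,99.29(2)
spleen,124.9,6,99.23(2)
tumour,15.9,1,99.6(1)
tumour,15.9,2,99.4(1)
tumour,15.9,3,99.2(1)
tumour,15.9,4,99.5(1)
tumour,15.9,5,99.7(1)
tumour,15.9,6,94.8(1)
cortex-L,90.9,1,97.69(2)
cortex-L,90.9,2,96.48(2)
cortex-L,90.9,3,98.92(2)
cortex-L,90.9,4,98.14(2)
cortex-L,90.9,5,98.33(2)
cortex-L,90.9,6,98.40(2)
medulla-L,42.9,1,99.05(5)
medulla-L,42.9,2,97.19(5)
medulla-L,42.9,3,102.04(5)
medulla-L,42.9,4,97.47(5)
medulla-L,42.9,5,97.72(5)
medulla-L,42.9,6,97.19(5)
cortex-R,75.7,1,99.29(3)
cortex-R,75.7,2,98.89(3)
cortex-R,75.7,3,99.59(3)
cortex-R,75.7,4,98.65(3)
cortex-R,75.7,5,99.48(3)
cortex-R,75.7,6,98.72(3)
medulla-R,35.7,1,96.20(6)
medulla-R,35.7,2,97.06(6)
medulla-R,35.7,3,96.56(6)
medulla-R,35.7,4,96.45(6)
medulla-R,35.7,5,97.32(6)
medulla-R,35.7,6,97.60(6)
background,8297,1,98.25(3)
background,8297,2,98.25(3)
background,8297,3,98.25(3)
background,8297,4,98.35(3)
background,8297,5,98.28(3)
background,8297,6,98.24(3)
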