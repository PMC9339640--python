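subject,plan,structure,median_pct
m1,SOC,bowel,28.3
m2,SOC,bowel,27.4
m3,SOC,bowel,8.6
m4,SOC,bowel,11.9
m5,SOC,bowel,9.7
m1,3D,bowel,37.5
m2,3D,bowel,38.0
m3,3D,bowel,24.2
m4,3D,bowel,22.5
m5,3D,bowel,36.3
m1,SOC,heart,6.5
m2,SOC,heart,5.0
m3,SOC,heart,20.3
m4,SOC,heart,18.7
m5,SOC,heart,12.4
m1,3D,heart,11.1
m2,3D,heart,9.3
m3,3D,heart,11.3
m4,3D,heart,9.2
m5,3D,heart,9.1
m1,SOC,kidneys,0.9
m2,SOC,kidneys,1.4
m3,SOC,kidneys,2.3
m4,SOC,kidneys,1.6
m5,SOC,kidneys,1.6
m1,3D,kidneys,91.3
m2,3D,kidneys,70.0
m3,3D,kidneys,89.0
m4,3D,kidneys,76.3
m5,3D,kidneys,81.3
m1,SOC,lungs,4.8
m2,SOC,lungs,4.6
m3,SOC,lungs,4.7
m4,SOC,lungs,4.1
m5,SOC,lungs,2.9
m1,3D,lungs,58.3
m2,3D,lungs,43.8
m3,3D,lungs,48.3
m4,3D,lungs,53.8
m5,3D,lungs,58.8
m1,SOC,liver,2.5
m2,SOC,liver,1.6
m3,SOC,liver,1.4
m4,SOC,liver,3.1
m5,SOC,liver,2.8
m1,3D,liver,22.5
m2,3D,liver,13.8
m3,3D,liver,9.8
m4,3D,liver,18.8
m5,3D,liver,23.8
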