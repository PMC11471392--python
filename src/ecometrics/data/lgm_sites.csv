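site,age_kya,fossil_rbl_mean,fossil_rbl_sd,modern_rbl_mean,modern_rbl_sd,paleo_habitat,modern_habitat,predicted_ap_mm,modern_ap_mm,predicted_mat_c,modern_mat_c
"Friesenhahn Cave, TX",20-10,0.74,0.19,0.64,0.12,Grassland,Grassland,1434.39,844,22.91,19.6
"Little Box Elder Cave, WY",24-10,0.73,0.16,0.66,0.12,"Conifer, boreal",Grassland,810.61,425,24.53,3.5
"New Trout Cave, WV",31.1-16.8,0.68,0.07,0.67,0.12,"Boreal, deciduous",Cold deciduous,623.98,1003,8.49,9.6
"Brynjulfson Cave, MO",34.6-9.4,0.64,0.08,0.66,0.12,Boreal,Cold deciduous,815.37,980,6.58,12.7
"January Cave, AB",35-23.1,0.70,0.04,0.72,0.16,"Conifer, boreal, tundra",Subpolar evergreen,216.74,572,6.77,1.6
"Anderson Pit, IN",40-10,0.61,0.10,0.66,0.14,Cold deciduous,Cold deciduous,135.33,1150,-16.7,11.9
"McKittrick, CA",40-10,0.75,0.18,0.69,0.16,Open deciduous,Xeromorphic shrubland,512.67,302,25.12,16.1
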