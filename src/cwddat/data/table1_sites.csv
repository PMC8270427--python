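site,state,latitude_deg,longitude_deg,elevation_m,MAT_C,MAP_mm,soil_series,forest_type,use,LAI_m2_m2
Caspar Creek,CA,39.3726,-123.7063,240,10.8,1175.4,Vanda-mme,Douglas fir,validation,3.5
Coweeta,NC,35.0467,-83.4574,910,12.2,2259.2,Evard-Cowee,Oak-hickory,calibration,5.5
Duke,NC,33.9760,-79.0924,170,15.8,1434.8,Appling,Loblolly-shortleaf pine,validation,2.5
Fraser,CO,39.9296,-105.8698,2710,2.9,576.4,Herd-Frisco,Fir-spruce,validation,2.5
Marcell,MN,47.5057,-93.4861,430,3.7,670.6,Cutaway,White-red-jack pine,calibration,2.2
San Dimas,CA,34.2064,-117.7615,670,17.7,523.1,Trigo,Sparse Shrub,calibration,0.1
Santee,SC,33.1482,-79.7910,8,18.6,1673.9,Wahee,Loblolly-shortleaf pine,calibration,2.5
Sierra Ancha,AZ,33.8039,-110.9159,2220,11.2,717.8,Sobega,Ponderosa pine,validation,2.2
Tenderfoot Creek,MT,46.9236,-110.8697,2130,2.2,857.8,Jeff-lake-Yellow-mule-Lonniebee,Lodgepole pine,validation,2.2
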