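site,position,species,size_class,diameter_cm,mass_kg,density_g_cm3,length_m
Caspar Creek,down,1,1,5.96,55.35,0.47,1.0
Caspar Creek,down,1,2,8.76,35.74,0.47,1.0
Caspar Creek,down,2,2,10.72,71.13,0.53,2.0
Caspar Creek,down,2,3,17.89,210.54,0.52,2.0
Caspar Creek,down,2,4,25.40,274.89,0.51,2.0
Caspar Creek,stand,2,2,12.10,145.37,0.53,2.0
Caspar Creek,stand,2,3,18.70,72.27,0.49,2.0
Caspar Creek,stand,2,4,24.20,318.57,0.54,2.0
Coweeta,down,1,1,6.16,50.04,0.46,1.0
Coweeta,down,1,2,8.84,54.29,0.46,1.0
Coweeta,down,2,2,12.98,118.03,0.53,2.0
Coweeta,down,2,3,16.88,233.22,0.54,2.0
Coweeta,down,2,4,24.57,142.78,0.56,2.0
Coweeta,stand,2,2,12.47,131.50,0.53,2.0
Coweeta,stand,2,3,18.10,188.99,0.52,2.0
Coweeta,stand,2,4,24.41,176.84,0.52,2.0
Duke,down,1,1,6.09,55.80,0.46,1.0
Duke,down,1,2,8.88,39.03,0.45,1.0
Duke,down,2,1,6.33,2.91,0.47,2.0
Duke,down,2,2,11.55,152.72,0.47,2.0
Duke,down,2,3,17.86,519.20,0.53,2.0
Duke,down,2,4,25.85,61.89,0.65,2.0
Duke,stand,2,2,12.79,95.07,0.55,2.0
Duke,stand,2,3,18.34,337.59,0.52,2.0
Duke,stand,2,4,27.73,115.41,0.52,2.0
Fraser,down,1,1,5.97,56.84,0.46,1.0
Fraser,down,1,2,8.71,25.12,0.45,1.0
Fraser,down,2,2,12.05,123.11,0.54,2.0
Fraser,down,2,3,17.71,190.58,0.54,2.0
Fraser,down,2,4,26.35,224.18,0.57,2.0
Fraser,stand,2,2,11.95,98.86,0.52,2.0
Fraser,stand,2,3,18.52,254.88,0.53,2.0
Fraser,stand,2,4,25.13,190.15,0.53,2.0
Marcell,down,1,1,6.04,51.11,0.48,1.0
Marcell,down,1,2,8.23,42.14,0.46,1.0
Marcell,down,2,2,12.75,124.52,0.53,2.0
Marcell,down,2,3,18.68,276.51,0.52,2.0
Marcell,down,2,4,25.63,89.62,0.49,2.0
Marcell,stand,2,2,12.72,168.25,0.53,2.0
Marcell,stand,2,3,17.64,162.53,0.54,2.0
Marcell,stand,2,4,24.88,104.46,0.61,2.0
San Dimas,down,1,1,6.05,57.59,0.47,1.0
San Dimas,down,1,2,8.42,27.78,0.45,1.0
San Dimas,down,2,2,11.89,91.09,0.53,2.0
San Dimas,down,2,3,18.61,252.68,0.53,2.0
San Dimas,down,2,4,25.71,196.79,0.52,2.0
San Dimas,stand,2,2,11.80,59.63,0.54,2.0
San Dimas,stand,2,3,18.14,351.20,0.55,2.0
San Dimas,stand,2,4,24.77,96.27,0.56,2.0
Santee,down,1,1,6.23,53.12,0.46,1.0
Santee,down,1,2,8.62,41.30,0.46,1.0
Santee,down,2,2,8.85,4.95,0.52,2.0
Santee,down,2,3,18.55,1101.15,0.53,2.0
Santee,down,2,4,24.42,319.22,0.54,2.0
Santee,stand,2,2,13.05,79.96,0.50,2.0
Santee,stand,2,3,19.16,297.43,0.53,2.0
Santee,stand,2,4,24.93,290.02,0.55,2.0
Sierra Ancha,down,1,1,5.59,38.34,0.49,1.0
Sierra Ancha,down,1,2,8.90,64.66,0.46,1.0
Sierra Ancha,down,2,2,13.27,50.41,0.54,2.0
Sierra Ancha,down,2,3,19.31,472.78,0.54,2.0
Sierra Ancha,down,2,4,23.42,131.45,0.56,2.0
Sierra Ancha,stand,2,2,13.08,108.58,0.54,2.0
Sierra Ancha,stand,2,3,20.16,282.15,0.55,2.0
Sierra Ancha,stand,2,4,25.26,310.22,0.56,2.0
Tenderfoot Creek,down,1,1,6.22,47.35,0.46,1.0
Tenderfoot Creek,down,1,2,8.76,54.62,0.47,1.0
Tenderfoot Creek,down,2,2,12.31,102.97,0.56,2.0
Tenderfoot Creek,down,2,3,18.98,297.57,0.54,2.0
Tenderfoot Creek,down,2,4,24.80,190.69,0.55,2.0
Tenderfoot Creek,stand,2,2,11.48,119.20,0.53,2.0
Tenderfoot Creek,stand,2,3,17.81,211.35,0.53,2.0
Tenderfoot Creek,stand,2,4,24.75,94.97,0.54,2.0
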