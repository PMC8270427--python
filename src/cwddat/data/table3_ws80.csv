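position,species,size_class,mass_Mg_ha
down,2,1,0
down,1,1,0
stand,2,1,0
stand,1,1,0
down,2,2,3.90
down,1,2,7.30
stand,2,2,0
stand,1,2,0.50
down,2,3,11.21
down,1,3,11.98
stand,2,3,0.50
stand,1,3,1.01
down,2,4,20.90
down,1,4,17.19
stand,2,4,2.49
stand,1,4,1.02
down,2,5,23.80
down,1,5,12.00
stand,2,5,3.49
stand,1,5,1.01
down,2,6,10.20
down,1,6,0
stand,2,6,1.50
stand,1,6,0
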