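common_name,species_name,mass_kg,outer_radius,radius_unit,n_lamellae,lamellar_thickness,thickness_unit,class,habitat,reported_peak_hz,reported_bandwidth_hz,source
cat,Felis catus,4.04,255.6,um,30,0.24,um,mammal,terrestrial,48,142.9,published morphometry
crocodile,Crocodylus niloticus,386,75.14,um,10,3.18,um,reptile,,43,168.4,published micrograph
dog,Canis familiaris,46.5,1971.24,px,10,10.92,px,mammal,terrestrial,21,174.7,published micrograph without scale bar (pixels)
duck,Anas platyrhynchos,1.15,43.9,um,15,0.91,um,bird,,41.5,154,lamella count approximated from published text
elephant,Elephas maximus,4082,317.3,um,26,6.13,um,mammal,terrestrial,48,177.6,published micrograph
emu,Dromaius novaehollandiae,37.9,61,um,15,1.77,um,bird,,40,168.5,published micrograph
frog,Rana esculata,0.04,59.99,um,15,1.6,um,amphibian,,30,160.5,published micrograph
goose,Anserini,4.38,66.02,um,30,0.51,um,bird,,165,228,published micrograph
human,Homo sapien,62.1,190,um,28,1.1,um,mammal,terrestrial,137.5,683.7,published morphometry
kangaroo,Macropus giganteus,90.7,240.7,um,15,4.14,um,mammal,terrestrial,44,154.4,published micrograph
mole,Scapanus orarius,0.055,4.6,um,10,0.11,um,mammal,terrestrial,40.5,168.3,radius re-measured from source micrograph
monkey,Ateles fusciceps,1.8,1720.9,px,10,16.92,px,mammal,terrestrial,42,178.2,published micrograph without scale bar (pixels)
mouse,Mus musculus,0.0193,54.67,um,12,2.77,um,mammal,terrestrial,40,180,published micrograph
ostrich,Struthio camelus,107,37.51,um,7,3.2,um,bird,,20.5,170.3,published micrograph
porpoise,Phocoena phocoena,54.4,18.6,um,10,0.89,um,mammal,aquatic,41.5,200,published micrograph
rat,Rattus,0.23,92.67,um,18,1.97,um,mammal,terrestrial,43,137.7,micrographs provided by B. Guclu
rooster,Gallus gallus,3.45,203.8,px,8,4.57,px,bird,,42,177.3,published micrograph without scale bar (pixels)
snake,Elaphe quadrivirgata,0.33,977.6,px,18,5.3,px,reptile,,45,146.4,published micrograph without scale bar (pixels)
whale,Eschrichtius robustus,36000,74.02,um,9,3.1,um,mammal,aquatic,42,188.5,published micrograph
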