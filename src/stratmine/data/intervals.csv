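name,rank,parent,t_old,t_young
Phanerozoic,eon,,538.8,0
Paleozoic,era,Phanerozoic,538.8,251.902
Mesozoic,era,Phanerozoic,251.902,66.0
Cenozoic,era,Phanerozoic,66.0,0
Cambrian,period,Paleozoic,538.8,485.4
Ordovician,period,Paleozoic,485.4,443.8
Silurian,period,Paleozoic,443.8,419.2
Devonian,period,Paleozoic,419.2,358.9
Carboniferous,period,Paleozoic,358.9,298.9
Permian,period,Paleozoic,298.9,251.902
Triassic,period,Mesozoic,251.902,201.4
Jurassic,period,Mesozoic,201.4,145.0
Cretaceous,period,Mesozoic,145.0,66.0
Paleogene,period,Cenozoic,66.0,23.03
Neogene,period,Cenozoic,23.03,2.58
Quaternary,period,Cenozoic,2.58,0
Terreneuvian,epoch,Cambrian,538.8,521.0
Cambrian Series 2,epoch,Cambrian,521.0,509.0
Miaolingian,epoch,Cambrian,509.0,497.0
Furongian,epoch,Cambrian,497.0,485.4
Lower Ordovician,epoch,Ordovician,485.4,470.0
Middle Ordovician,epoch,Ordovician,470.0,458.4
Upper Ordovician,epoch,Ordovician,458.4,443.8
Llandovery,epoch,Silurian,443.8,433.4
Wenlock,epoch,Silurian,433.4,427.4
Ludlow,epoch,Silurian,427.4,423.0
Pridoli,epoch,Silurian,423.0,419.2
Lower Devonian,epoch,Devonian,419.2,393.3
Middle Devonian,epoch,Devonian,393.3,382.7
Upper Devonian,epoch,Devonian,382.7,358.9
Mississippian,epoch,Carboniferous,358.9,323.2
Pennsylvanian,epoch,Carboniferous,323.2,298.9
Cisuralian,epoch,Permian,298.9,273.01
Guadalupian,epoch,Permian,273.01,259.51
Lopingian,epoch,Permian,259.51,251.902
Lower Triassic,epoch,Triassic,251.902,247.2
Middle Triassic,epoch,Triassic,247.2,237.0
Upper Triassic,epoch,Triassic,237.0,201.4
Lower Jurassic,epoch,Jurassic,201.4,174.7
Middle Jurassic,epoch,Jurassic,174.7,163.5
Upper Jurassic,epoch,Jurassic,163.5,145.0
Lower Cretaceous,epoch,Cretaceous,145.0,100.5
Upper Cretaceous,epoch,Cretaceous,100.5,66.0
Paleocene,epoch,Paleogene,66.0,56.0
Eocene,epoch,Paleogene,56.0,33.9
Oligocene,epoch,Paleogene,33.9,23.03
Miocene,epoch,Neogene,23.03,5.333
Pliocene,epoch,Neogene,5.333,2.58
Pleistocene,epoch,Quaternary,2.58,0.0117
Holocene,epoch,Quaternary,0.0117,0
Fortunian,stage,Terreneuvian,538.8,529.0
Cambrian Stage 2,stage,Terreneuvian,529.0,521.0
Cambrian Stage 3,stage,Cambrian Series 2,521.0,514.0
Cambrian Stage 4,stage,Cambrian Series 2,514.0,509.0
Wuliuan,stage,Miaolingian,509.0,504.5
Drumian,stage,Miaolingian,504.5,500.5
Guzhangian,stage,Miaolingian,500.5,497.0
Paibian,stage,Furongian,497.0,494.0
Jiangshanian,stage,Furongian,494.0,489.5
Cambrian Stage 10,stage,Furongian,489.5,485.4
Tremadocian,stage,Lower Ordovician,485.4,477.7
Floian,stage,Lower Ordovician,477.7,470.0
Dapingian,stage,Middle Ordovician,470.0,467.3
Darriwilian,stage,Middle Ordovician,467.3,458.4
Sandbian,stage,Upper Ordovician,458.4,453.0
Katian,stage,Upper Ordovician,453.0,445.2
Hirnantian,stage,Upper Ordovician,445.2,443.8
Rhuddanian,stage,Llandovery,443.8,440.8
Aeronian,stage,Llandovery,440.8,438.5
Telychian,stage,Llandovery,438.5,433.4
Sheinwoodian,stage,Wenlock,433.4,430.5
Homerian,stage,Wenlock,430.5,427.4
Gorstian,stage,Ludlow,427.4,425.6
Ludfordian,stage,Ludlow,425.6,423.0
Lochkovian,stage,Lower Devonian,419.2,410.8
Pragian,stage,Lower Devonian,410.8,407.6
Emsian,stage,Lower Devonian,407.6,393.3
Eifelian,stage,Middle Devonian,393.3,387.7
Givetian,stage,Middle Devonian,387.7,382.7
Frasnian,stage,Upper Devonian,382.7,372.2
Famennian,stage,Upper Devonian,372.2,358.9
Tournaisian,stage,Mississippian,358.9,346.7
Visean,stage,Mississippian,346.7,330.9
Serpukhovian,stage,Mississippian,330.9,323.2
Bashkirian,stage,Pennsylvanian,323.2,315.2
Moscovian,stage,Pennsylvanian,315.2,307.0
Kasimovian,stage,Pennsylvanian,307.0,303.7
Gzhelian,stage,Pennsylvanian,303.7,298.9
Namurian,stage,Carboniferous,330.9,318.1
Asselian,stage,Cisuralian,298.9,293.52
Sakmarian,stage,Cisuralian,293.52,290.1
Artinskian,stage,Cisuralian,290.1,283.5
Kungurian,stage,Cisuralian,283.5,273.01
Roadian,stage,Guadalupian,273.01,266.9
Wordian,stage,Guadalupian,266.9,264.28
Capitanian,stage,Guadalupian,264.28,259.51
Wuchiapingian,stage,Lopingian,259.51,254.14
Changhsingian,stage,Lopingian,254.14,251.902
Induan,stage,Lower Triassic,251.902,251.2
Olenekian,stage,Lower Triassic,251.2,247.2
Anisian,stage,Middle Triassic,247.2,242.0
Ladinian,stage,Middle Triassic,242.0,237.0
Carnian,stage,Upper Triassic,237.0,227.0
Norian,stage,Upper Triassic,227.0,208.5
Rhaetian,stage,Upper Triassic,208.5,201.4
Hettangian,stage,Lower Jurassic,201.4,199.5
Sinemurian,stage,Lower Jurassic,199.5,192.9
Pliensbachian,stage,Lower Jurassic,192.9,184.2
Toarcian,stage,Lower Jurassic,184.2,174.7
Aalenian,stage,Middle Jurassic,174.7,170.3
Bajocian,stage,Middle Jurassic,170.3,168.3
Bathonian,stage,Middle Jurassic,168.3,166.1
Callovian,stage,Middle Jurassic,166.1,163.5
Oxfordian,stage,Upper Jurassic,163.5,157.3
Kimmeridgian,stage,Upper Jurassic,157.3,152.1
Tithonian,stage,Upper Jurassic,152.1,145.0
Berriasian,stage,Lower Cretaceous,145.0,139.8
Valanginian,stage,Lower Cretaceous,139.8,132.6
Hauterivian,stage,Lower Cretaceous,132.6,125.77
Barremian,stage,Lower Cretaceous,125.77,121.4
Aptian,stage,Lower Cretaceous,121.4,113.0
Albian,stage,Lower Cretaceous,113.0,100.5
Cenomanian,stage,Upper Cretaceous,100.5,93.9
Turonian,stage,Upper Cretaceous,93.9,89.8
Coniacian,stage,Upper Cretaceous,89.8,86.3
Santonian,stage,Upper Cretaceous,86.3,83.6
Campanian,stage,Upper Cretaceous,83.6,72.1
Maastrichtian,stage,Upper Cretaceous,72.1,66.0
Danian,stage,Paleocene,66.0,61.6
Selandian,stage,Paleocene,61.6,59.2
Thanetian,stage,Paleocene,59.2,56.0
Ypresian,stage,Eocene,56.0,47.8
Lutetian,stage,Eocene,47.8,41.2
Bartonian,stage,Eocene,41.2,37.71
Priabonian,stage,Eocene,37.71,33.9
Rupelian,stage,Oligocene,33.9,27.82
Chattian,stage,Oligocene,27.82,23.03
Aquitanian,stage,Miocene,23.03,20.44
Burdigalian,stage,Miocene,20.44,15.98
Langhian,stage,Miocene,15.98,13.82
Serravallian,stage,Miocene,13.82,11.63
Tortonian,stage,Miocene,11.63,7.246
Messinian,stage,Miocene,7.246,5.333
Zanclean,stage,Pliocene,5.333,3.6
Piacenzian,stage,Pliocene,3.6,2.58
Gelasian,stage,Pleistocene,2.58,1.8
Calabrian,stage,Pleistocene,1.8,0.774
Chibanian,stage,Pleistocene,0.774,0.129
Upper Pleistocene,stage,Pleistocene,0.129,0.0117
Meghalayan,stage,Holocene,0.0042,0
Northgrippian,stage,Holocene,0.0082,0.0042
Greenlandian,stage,Holocene,0.0117,0.0082
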