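species,common_name,mass_g,preparation,ch_vol_mm3,ch_vol_minus_feet_mm3
Goura victoria,Victoria crowned pigeon,1951,eviscerated,1487180,1436777
Streptopelia decaocto,Collared dove,201,intact,203875,196791
Columba livia,Rock dove,290,intact,115945,113074
Columba palumbus,Wood pigeon,305,intact,337993,328279
Ducula bicolor,Pied imperial pigeon,450,eviscerated,337377,329220
Petrophassa rufipennis,Chestnut-quilled rock pigeon,314,eviscerated,303511,286104
Otidiphaps nobilis,Pheasant pigeon,401,eviscerated,344368,329238
Nesoenas mayeri,Pink pigeon,200,eviscerated,197171,185981
Ducula sp.,Imperial pigeon,336,eviscerated,314985,305344
Caloenas nicobarica,Nicobar pigeon,539,eviscerated,383736,367753
Phaps chalcoptera,Common bronze-winged pigeon,249,intact,213953,208942
Ducula aenea,Green imperial pigeon,483,intact,348268,336968
Columba guinea,Speckled pigeon,158,intact,105156,102041
Zenaida graysoni,Socorro dove,176,eviscerated,105776,102441
Gallicolumba sp.,Bleeding heart dove,215,eviscerated,163764,152136
Phapitreron leucotis,White-eared brown dove,107,eviscerated,69424,67088
Ptilinopus sp.,Fruit dove,71,eviscerated,47816,46635
Ptilinopus superbus,Superb fruit dove,137,eviscerated,77882,74691
Treron vernans,Pink-necked green pigeon,167,eviscerated,104991,101984
Ocyphaps lophotes,Crested pigeon,107,intact,67451,64011
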