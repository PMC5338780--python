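species,prey_group,n_items,n_samples
Muraenolepis marmoratus,fish,2,2
Zanclorhynchus spinosus,fish,1,1
Gobionotothen acuta,fish,3,1
Lepidonotothen mizops,fish,32,6
Notothenia cyanobrancha,fish,92,21
Notothenia rossii,fish,1,1
Paranotothenia magellanica,fish,14,10
Nototheniidae sp.,fish,3,3
Harpagifer kerguelensis/spinosus,fish,54,11
Channichthys rhinoceratus,fish,1,1
Undetermined fish,fish,1,1
Polynoidae sp.,annelid,13,9
Benthoctopus thielei,cephalopod,5,4
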