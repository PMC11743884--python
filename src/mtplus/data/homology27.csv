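species,atlas_label,homolog,lobe
human,PMv,PMv,frontal
human,PMd,PMd,frontal
human,pre-SMA,pre-SMA,frontal
human,BA44,BA44,frontal
human,BA45,BA45,frontal
human,BA46,BA46,frontal
human,FEF,FEF,frontal
human,AIP,AIP,parietal
human,LIP,LIP,parietal
human,VIP,VIP,parietal
human,MIP,MIP,parietal
human,PFm,PFm,parietal
human,V6A,V6A,parietal
human,BA5,BA5,parietal
human,BA7,BA7,parietal
human,TE,TE,temporal
human,TEO,TEO,temporal
human,STP,STP,temporal
human,STS,STS,temporal
human,parabelt,parabelt,temporal
human,temporal-pole,temporal-pole,temporal
human,V1,V1,occipital
human,V2,V2,occipital
human,V3,V3,occipital
human,V3A,V3A,occipital
human,V4,V4,occipital
human,V4t,V4t,occipital
macaque,F5,PMv,frontal
macaque,F2,PMd,frontal
macaque,F6,pre-SMA,frontal
macaque,44,BA44,frontal
macaque,45A,BA45,frontal
macaque,46d,BA46,frontal
macaque,FEF,FEF,frontal
macaque,AIP,AIP,parietal
macaque,LIP,LIP,parietal
macaque,VIP,VIP,parietal
macaque,MIP,MIP,parietal
macaque,PFG,PFm,parietal
macaque,V6A,V6A,parietal
macaque,PE,BA5,parietal
macaque,PG,BA7,parietal
macaque,TE,TE,temporal
macaque,TEO,TEO,temporal
macaque,STP,STP,temporal
macaque,STS,STS,temporal
macaque,parabelt,parabelt,temporal
macaque,temporal-pole,temporal-pole,temporal
macaque,V1,V1,occipital
macaque,V2,V2,occipital
macaque,V3,V3,occipital
macaque,V3A,V3A,occipital
macaque,V4,V4,occipital
macaque,V4t,V4t,occipital
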