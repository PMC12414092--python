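id,name,sequence,svm_score,prediction,hydrophobicity,amphipathicity,mol_wt,na4vss,sopep_energy
2606,Pep1,PDPECYYS,-0.12,Non-Toxin,-0.21,0.16,973.11,-26.8,-2.80309
2607,Pep2,PDPECYYT,-0.18,Non-Toxin,-0.2,0.16,987.14,-25.8,-2.36648
3284,Pep3,PEPDCYYN,-0.29,Non-Toxin,-0.26,0.16,1000.14,-36.5,-7.09487
359,Pep4,GDGECYYN,-0.17,Non-Toxin,-0.2,0.16,920.02,-38.4,-1.26908
2385,Pep5,PDPDCYYQ,-0.25,Non-Toxin,-0.27,0.16,1000.14,-40.2,-2.49303
658,Pep6,GDPDQWYC,-0.18,Non-Toxin,-0.2,0.16,983.12,-57,-3.63035
2159,Pep7,PDGECYYN,-0.25,Non-Toxin,-0.23,0.16,960.08,-36.9,-1.71421
2594,Pep8,PDPECWYN,-0.15,Non-Toxin,-0.21,0.16,1023.18,-35.9,-2.46027
135,Pep9,GDGDCYYQ,-0.28,Non-Toxin,-0.22,0.16,920.02,-44.2,-1.91976
68,Pep10,GDPDQYWC,-0.22,Non-Toxin,-0.2,0.16,983.12,-56.7,-3.73611
1034,Pep11,GEGDCYYN,-0.23,Non-Toxin,-0.2,0.16,920.02,-40.5,-2.21242
834,Pep12,PEGDCYYN,-0.18,Non-Toxin,-0.23,0.16,960.08,-39,-2.70096
580,Pep13,GDPDCYWQ,-0.15,Non-Toxin,-0.2,0.16,983.12,-42.9,-2.40548
2370,Pep14,PDPDCWYQ,-0.27,Non-Toxin,-0.23,0.16,1023.18,-41.7,-2.45375
2609,Pep15,PDPECYYN,-0.11,Non-Toxin,-0.26,0.16,1000.14,-34.4,-2.36291
1930,Pep16,PDGDCYWQ,-0.22,Non-Toxin,-0.2,0.16,983.12,-44,-2.9538
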