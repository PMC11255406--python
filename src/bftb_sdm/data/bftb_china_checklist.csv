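species_name,genus,family,superfamily,tribe,host_plants,region
Mecistoscelis scirteloides,Mecistoscelis,Miridae,Miroidea,,,china
Mystilus priamus,Mystilus,Miridae,Miroidea,,,china
Elthemidea picea,Elthemidea,Miridae,Miroidea,,Phyllostachys edulis,china
Elthemidea sichuanese,Elthemidea,Miridae,Miroidea,,Phyllostachys edulis,china
Pirkimerus japonicus,Pirkimerus,Blissidae,Lygaeoidea,,Phyllostachys edulis,china
Macropes robustus,Macropes,Blissidae,Lygaeoidea,,,china
Macropes harringtonae,Macropes,Blissidae,Lygaeoidea,,Phyllostachys edulis,china
Macropes maai,Macropes,Blissidae,Lygaeoidea,,Phyllostachys viridis,china
Iphicrates spinicaput,Iphicrates,Blissidae,Lygaeoidea,,Indocalamus migoi,china
Iphicrates weni,Iphicrates,Blissidae,Lygaeoidea,,Sinocalamus beecheyanus,china
Dimorphopterus japonicus,Dimorphopterus,Blissidae,Lygaeoidea,,Phyllostachys viridis,china
Bochrus foveatus,Bochrus,Blissidae,Lygaeoidea,,,china
Artemidorus pressus,Artemidorus,Heterogastridae,Lygaeoidea,,,china
Malcus setosus,Malcus,Malcidae,Lygaeoidea,,,china
Yemmalysus parallelus,Yemmalysus,Berytidae,Lygaeoidea,,Ampelocalamus actinotrichus,china
Phenacantha viridipennis,Phenacantha,Colobathristidae,Lygaeoidea,,Dinochloa utilis,china
Phenacantha bicolor,Phenacantha,Colobathristidae,Lygaeoidea,,,china
Acestra sinica,Acestra,Alydidae,Coreoidea,Micrelytrini,,china
Acestra malayana,Acestra,Alydidae,Coreoidea,Micrelytrini,,china
Anacestra hirticornis,Anacestra,Alydidae,Coreoidea,Micrelytrini,Fargesia sp.,china
Anacestra spiniger,Anacestra,Alydidae,Coreoidea,Micrelytrini,,china
Anacestra sp.,Anacestra,Alydidae,Coreoidea,Micrelytrini,,china
Distachys vulgaris,Distachys,Alydidae,Coreoidea,Micrelytrini,,china
Marcius longirostris,Marcius,Alydidae,Coreoidea,Micrelytrini,,china
Marcius nigrospinosus,Marcius,Alydidae,Coreoidea,Micrelytrini,,china
Marcius sichuananus,Marcius,Alydidae,Coreoidea,Micrelytrini,,china
Marcius sp.,Marcius,Alydidae,Coreoidea,Micrelytrini,,china
Tuberculiformia subinermis,Tuberculiformia,Alydidae,Coreoidea,Micrelytrini,,china
Paramarcius puncticeps,Paramarcius,Alydidae,Coreoidea,Micrelytrini,,china
Notobitus excellens,Notobitus,Coreidae,Coreoidea,Cloresmini,Dendrocalamus sp.,china
Notobitus sexguttatus,Notobitus,Coreidae,Coreoidea,Cloresmini,Bambusa textilis;Bambusa chungii,china
Notobitus elongatus,Notobitus,Coreidae,Coreoidea,Cloresmini,,china
Notobitus meleagris,Notobitus,Coreidae,Coreoidea,Cloresmini,Bambusa textilis;Phyllostachys viridis,china
Notobitus montanus,Notobitus,Coreidae,Coreoidea,Cloresmini,Phyllostachys edulis,china
Notobitiella elegans,Notobitiella,Coreidae,Coreoidea,Cloresmini,Dendrocalamus sp.,china
Notobitiella bispina,Notobitiella,Coreidae,Coreoidea,Cloresmini,,china
Cloresmus yunnanensis,Cloresmus,Coreidae,Coreoidea,Cloresmini,Dendrocalamus sp.,china
Cloresmus pulchellus,Cloresmus,Coreidae,Coreoidea,Cloresmini,Dendrocalamus sp.,china
Cloresmus modestus,Cloresmus,Coreidae,Coreoidea,Cloresmini,Dendrocalamus sp.,china
Cloresmus sp1.,Cloresmus,Coreidae,Coreoidea,Cloresmini,,china
Cloresmus sp2.,Cloresmus,Coreidae,Coreoidea,Cloresmini,Phyllostachys edulis,china
Cloresmus similis,Cloresmus,Coreidae,Coreoidea,Cloresmini,,china
Manocoreus marginatus,Manocoreus,Coreidae,Coreoidea,Manocoreini,,china
Manocoreus yunnanensis,Manocoreus,Coreidae,Coreoidea,Manocoreini,,china
Manocoreus vulgaris,Manocoreus,Coreidae,Coreoidea,Manocoreini,,china
Manocoreus montanus,Manocoreus,Coreidae,Coreoidea,Manocoreini,,china
Manocoreus astinus,Manocoreus,Coreidae,Coreoidea,Manocoreini,,china
Fracastorius cornutus,Fracastorius,Coreidae,Coreoidea,,,china
Homoeocerus striicornis,Homoeocerus,Coreidae,Coreoidea,,Phyllostachys spp.,china
Cressona valida,Cressona,Pentatomidae,Pentatomoidea,,,china
Cressona divaricata,Cressona,Pentatomidae,Pentatomoidea,,,china
Vitruvius insignis,Vitruvius,Pentatomidae,Pentatomoidea,,,china
Aenaria pinchii,Aenaria,Pentatomidae,Pentatomoidea,,Phyllostachys edulis,china
Aenaria lewisi,Aenaria,Pentatomidae,Pentatomoidea,,Pleioblastus amarus,china
Aenaria bivitta,Aenaria,Pentatomidae,Pentatomoidea,,,china
Aenaria zhangi,Aenaria,Pentatomidae,Pentatomoidea,,,china
Halyabbas unicolor,Halyabbas,Pentatomidae,Pentatomoidea,,Phyllostachys edulis,china
Brachymna tenuis,Brachymna,Pentatomidae,Pentatomoidea,,,china
Brachymna bificeps,Brachymna,Pentatomidae,Pentatomoidea,,,china
Brachymna humerata,Brachymna,Pentatomidae,Pentatomoidea,,,china
Zouicoris elegans,Zouicoris,Pentatomidae,Pentatomoidea,,,china
Critheus lineatifrons,Critheus,Pentatomidae,Pentatomoidea,,Bambusa stenostachys,china
Critheus indicus,Critheus,Pentatomidae,Pentatomoidea,,,china
Hippotiscus dorsalis,Hippotiscus,Pentatomidae,Pentatomoidea,,Phyllostachys edulis,china
Paterculus parvus,Paterculus,Pentatomidae,Pentatomoidea,,,china
Paterculus elatus,Paterculus,Pentatomidae,Pentatomoidea,,Pleioblastus amarus,china
Paterculus aberrans,Paterculus,Pentatomidae,Pentatomoidea,,,china
Dabessus albovittatus,Dabessus,Pentatomidae,Pentatomoidea,,,china
Dunnius minor,Dunnius,Pentatomidae,Pentatomoidea,,,china
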