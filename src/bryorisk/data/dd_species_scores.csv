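species,risk_mam1,risk_mam2,reported_verdict
Acaulon piligerum,0.069,0.107,Non-threatened
Acroporium consanguineum,0.304,0.417,Threatened
Aloina humilis,0.304,0.368,Threatened
Andreaea alpestris,0.304,0.413,Threatened
Andreaea vaginalis,0.203,,Non-threatened
Barbula lavardei,0.453,,Threatened
Barbula macassarensis,0.203,,Non-threatened
Barbula novogranatensis,0.203,0.373,Possibly Threatened
Barbula stenocarpa,0.304,0.356,Threatened
Bartramia aprica,0.304,0.313,Threatened
Brachymenium curvitheca,0.203,0.072,Non-threatened
Braunia schimperi,0.304,0.313,Threatened
Bryum demaretianum,0.255,,Threatened
Bryum enisseense,0.304,0.232,Threatened
Callicostella mosenii,,0.200,Threatened
Chionoloma minus,0.255,,Threatened
Cinclidotus x vivesii,0.453,,Threatened
Coscinodon humilis,0.203,0.411,Possibly Threatened
Didymodon soaresii,0.203,,Non-threatened
Distichophyllum telmaphila,,0.297,Threatened
Drepanocladus halli,0.203,,Non-threatened
Drepanocladus sparsus,,0.274,Threatened
Entosthodon clavatus,0.304,0.363,Threatened
Grimmia arenaria,0.203,0.407,Possibly Threatened
Grimmia laevigata,0.203,0.405,Possibly Threatened
Helicoblepharum daltoniaceum,0.203,0.271,Possibly Threatened
Hyophila bingeri,0.203,0.419,Possibly Threatened
Hyophila latifolia,0.203,0.357,Possibly Threatened
Hypnella punctata,0.453,,Threatened
Hypnum aemulans,0.453,,Threatened
Isopterygium plumicaule,0.304,0.380,Threatened
Lepidopilidium cespitosum,0.203,0.201,Possibly Threatened
Orthotrichum cambrense,0.304,0.420,Threatened
Philonotis striatula,0.304,0.031,Possibly Threatened
Pseudoleskea dispersa,0.453,,Threatened
Pterygoneurum papillosum,0.153,0.208,Possibly Threatened
Pterygophyllum chonoticum,,0.198,Threatened
Racopilum crassicuspidatum,,0.230,Threatened
Rhynchostegiella tubulosa,0.304,,Threatened
Sematophyllum fragilirostrum,0.203,0.273,Possibly Threatened
Taxithelium ramivagum,0.203,0.323,Possibly Threatened
Trematodon brevifolius,0.304,0.338,Threatened
Weissia multicapsularis,0.153,0.227,Possibly Threatened
Wijkia jungneri,0.041,0.023,Non-threatened
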