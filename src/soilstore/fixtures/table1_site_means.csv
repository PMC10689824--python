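sample_id,site_id,soil_type,fertility_class,moisture_pct,ph,total_organic_c,soluble_organic_c,total_n,total_p,mehlich_po4,mbc,substrate_cp_mass,mbp,microbial_cp_mass,microbial_cp_molar,phosphomonoesterase,phosphodiesterase,glucosidase,glucosidase_phosphatase_ratio,plfa_total,plfa_bacterial,plfa_fungal,nlfa_c,phb_c,trehalose_c,nlfa_per_soc,phb_per_soc,trehalose_per_soc
basalt_site_1,basalt_site_1,basalt,fertile,41.0,5.62,0.0428,102,2577,620,1.96,553,59.6,38.2,29.4,75.6,952,296,205,0.11,67.0,42.7,9.5,22.3,33.4,0.9,532,807,22.1
basalt_site_2,basalt_site_2,basalt,fertile,30.6,4.82,0.0305,53,2240,243,0.67,273,80.0,28.5,9.7,25.1,270,229,61,0.17,42.5,27.4,5.4,10.3,15.1,4.3,339,514,138
shale_site_1,shale_site_1,shale,fertile,17.1,4.82,0.0239,68,1766,168,1.41,327,53.6,22.4,14.4,37.1,381,162,229,0.41,42.1,23.2,7.8,14.3,20.5,41.0,603,858,1740
shale_site_2,shale_site_2,shale,fertile,35.9,5.27,0.0451,87,2765,164,2.48,419,53.2,38.1,10.5,27.1,1155,244,412,0.27,46.5,27.2,7.0,17.1,25.4,7.2,393,587,248
ironstone_site_1,ironstone_site_1,ironstone,infertile,16.3,5.19,0.012,66,750,131,0.03,203,2981,0.7,417,1075,513,307,97,0.08,15.5,7.0,3.5,14.6,36.1,0.8,1238,3114,68.3
ironstone_site_2,ironstone_site_2,ironstone,infertile,15.0,5.01,0.0141,48,1059,119,0.17,186,528,3.5,59.9,154,774,282,95,0.11,21.4,8.1,6.2,18.4,30.0,12.5,1431,2248,686
sandstone_site_1,sandstone_site_1,sandstone,infertile,14.1,5.00,0.0097,57,900,95,0.07,156,1266,3.3,43.5,112,630,245,54,0.13,15.2,6.4,3.5,9.9,18.7,1.0,1016,1924,98.2
sandstone_site_2,sandstone_site_2,sandstone,infertile,17.3,5.05,0.0162,62,851,36,0.17,235,636,13.2,78.7,203,931,407,160,0.07,24.1,9.5,6.0,20.5,41.0,1.7,1361,2605,165
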