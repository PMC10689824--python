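{
  "level": "site_mean",
  "n_records": 8,
  "provenance": "Published site means for the eight West Head surface-soil sites (four parent materials x two sites); per-SOC columns are stored as printed because they are means of replicate-level ratios, not ratios of the printed means.",
  "units": {
    "total_organic_c": "fraction of dry mass",
    "soluble_organic_c": "ug C g soil-1",
    "total_n": "ug N g soil-1",
    "total_p": "ug P g soil-1",
    "mehlich_po4": "ug P g soil-1",
    "mbc": "ug C g soil-1",
    "mbp": "ug P g soil-1",
    "plfa_total": "nmol g soil-1",
    "plfa_bacterial": "nmol g soil-1",
    "plfa_fungal": "nmol g soil-1",
    "nlfa_c": "ug C g soil-1",
    "phb_c": "ug C g soil-1",
    "trehalose_c": "ug C g soil-1",
    "phosphomonoesterase": "ug PNP g soil-1 h-1",
    "phosphodiesterase": "ug PNP g soil-1 h-1",
    "glucosidase": "ug PNP g soil-1 h-1",
    "nlfa_per_soc": "ug C g SOC-1",
    "phb_per_soc": "ug C g SOC-1",
    "trehalose_per_soc": "ug C g SOC-1"
  }
}
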