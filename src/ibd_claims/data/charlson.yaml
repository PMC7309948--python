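# Charlson comorbidity categories, Deyo-style ICD-9-CM prefix adaptation.
# A diagnosis code matches a category if it starts with any listed prefix
# (dots significant: "250.4" matches 250.40-250.43 but not 250.0x).
# Categories are prefix-disjoint; each matched category counts once.
myocardial_infarction:
  prefixes: ["410", "412"]
  weight: 1
congestive_heart_failure:
  prefixes: ["428"]
  weight: 1
peripheral_vascular_disease:
  prefixes: ["441", "443.9", "447.1", "785.4", "V43.4"]
  weight: 1
cerebrovascular_disease:
  prefixes: ["430", "431", "432", "433", "434", "435", "436", "437", "438"]
  weight: 1
dementia:
  prefixes: ["290"]
  weight: 1
chronic_pulmonary_disease:
  prefixes: ["490", "491", "492", "493", "494", "495", "496", "500", "501", "502", "503", "504", "505"]
  weight: 1
rheumatologic_disease:
  prefixes: ["710.0", "710.1", "710.4", "714.0", "714.1", "714.2", "714.81", "725"]
  weight: 1
peptic_ulcer_disease:
  prefixes: ["531", "532", "533", "534"]
  weight: 1
mild_liver_disease:
  prefixes: ["571.2", "571.4", "571.5", "571.6"]
  weight: 1
diabetes:
  prefixes: ["250.0", "250.1", "250.2", "250.3", "250.7"]
  weight: 1
diabetes_with_complications:
  prefixes: ["250.4", "250.5", "250.6"]
  weight: 2
hemiplegia_paraplegia:
  prefixes: ["342", "344.1"]
  weight: 2
renal_disease:
  prefixes: ["582", "583.0", "583.1", "583.2", "583.4", "583.6", "583.7", "585", "586", "588"]
  weight: 2
any_malignancy:
  prefixes: ["140", "141", "142", "143", "144", "145", "146", "147", "148", "149",
             "150", "151", "152", "153", "154", "155", "156", "157", "158", "159",
             "160", "161", "162", "163", "164", "165", "170", "171", "172", "174",
             "175", "176", "179", "180", "181", "182", "183", "184", "185", "186",
             "187", "188", "189", "190", "191", "192", "193", "194", "195",
             "200", "201", "202", "203", "204", "205", "206", "207", "208"]
  weight: 2
moderate_severe_liver_disease:
  prefixes: ["456.0", "456.1", "456.2", "572.2", "572.3", "572.4", "572.8"]
  weight: 3
metastatic_solid_tumor:
  prefixes: ["196", "197", "198", "199"]
  weight: 6
aids:
  prefixes: ["042", "043", "044"]
  weight: 6
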