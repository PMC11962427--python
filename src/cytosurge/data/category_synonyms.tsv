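# Clinical event category synonym map.
# Two tab-separated columns: alias<TAB>canonical category.
# Aliases are matched case-insensitively after stripping whitespace.
# Canonical categories: cancer_nmsc, cancer_invasive, cancer_other,
# cardiovascular, inflammatory, other.
cancer_nmsc	cancer_nmsc
nmsc	cancer_nmsc
non-melanoma skin cancer	cancer_nmsc
nonmelanoma skin cancer	cancer_nmsc
basal cell carcinoma	cancer_nmsc
bcc	cancer_nmsc
squamous cell carcinoma	cancer_nmsc
cutaneous squamous cell carcinoma	cancer_nmsc
cscc	cancer_nmsc
cancer_invasive	cancer_invasive
invasive cancer	cancer_invasive
melanoma	cancer_invasive
lung cancer	cancer_invasive
breast cancer	cancer_invasive
colon cancer	cancer_invasive
colorectal cancer	cancer_invasive
prostate cancer	cancer_invasive
lymphoma	cancer_invasive
leukemia	cancer_invasive
cancer_other	cancer_other
cancer	cancer_other
malignancy	cancer_other
cardiovascular	cardiovascular
cvd	cardiovascular
myocardial infarction	cardiovascular
stroke	cardiovascular
hypertension	cardiovascular
atrial fibrillation	cardiovascular
coronary artery disease	cardiovascular
heart failure	cardiovascular
inflammatory	inflammatory
arthritis	inflammatory
rheumatoid arthritis	inflammatory
gout	inflammatory
inflammatory bowel disease	inflammatory
pneumonia	inflammatory
bronchitis	inflammatory
diverticulitis	inflammatory
other	other
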