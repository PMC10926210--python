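"""Levin PAF arithmetic from printed table inputs.

Published per-SNP tables report the subcohort carrier counts and the Cox
hazard ratio; those two numbers fully determine the population attributable
fraction PAF = p(HR-1)/(p(HR-1)+1). No survival fitting is involved.
"""

from thrombopaf import paf_from_printed

table = paf_from_printed([
    {"label": "FVL rs6025 / women", "n_one_allele": 434, "n_two_alleles": 10,
     "n_total": 6909, "hr": 2.48},
    {"label": "FVL rs6025 / men", "n_one_allele": 420, "n_two_alleles": 5,
     "n_total": 6160, "hr": 2.17},
    {"label": "F2 rs1799963 / women", "n_one_allele": 85, "n_total": 6909,
     "hr": 1.17},
    {"label": "F2 rs1799963 / men", "n_one_allele": 88, "n_total": 6160,
     "hr": 1.79},
    {"label": "ABO rs8176719 / women", "n_one_allele": 3166,
     "n_two_alleles": 1056, "n_total": 6909, "hr": 1.33},
])
print(table[["label", "prevalence", "hr", "paf_percent"]].to_string(index=False))
print()
print("paf_percent is the fraction of disease attributable to carriership,")
print("as a percent of all cases, rounded to one decimal as tables print it.")
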