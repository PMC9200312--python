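"""Read and clean a raw summary-statistic file for LD-score regression.

Builds a small synthetic raw file (odds ratios, mixed column names, a
duplicate record, a strand-ambiguous SNP and one variant inside the APOE
block), then applies the standard cleaning: synonym-based column resolution,
OR -> log-odds, HapMap3-style reference intersection with allele alignment,
MAF/INFO filters and MHC/APOE region exclusion.
"""

import tempfile
from pathlib import Path

import pandas as pd

from proxymeta import munge, read_sumstats

raw = """SNP CHR BP EA NEA OR SE EAF INFO N
rs1 1 1000000 A G 1.05 0.02 0.30 0.98 60000
rs2 1 2000000 A T 0.97 0.02 0.40 0.99 60000
rs3 19 45500000 C T 1.50 0.03 0.20 0.97 60000
rs4 2 3000000 G A 1.02 0.02 0.25 0.95 60000
rs5 2 4000000 C T 0.99 0.02 0.45 0.80 60000
rs1 1 1000000 A G 1.05 0.02 0.30 0.98 60000
"""
path = Path(tempfile.mkdtemp()) / "raw.sumstats"
path.write_text(raw)

table = read_sumstats(path)
print("after reading:", len(table), "records;", table.attrs["log"])

reference = pd.DataFrame(
    {"SNP": [f"rs{i}" for i in range(1, 6)], "A1": ["A", "A", "C", "A", "C"],
     "A2": ["G", "T", "T", "G", "T"]}
)
clean = munge(table, reference)
print("after munging:", len(clean), "records;", clean.attrs["log"])
print(clean[["SNP", "CHR", "BP", "A1", "A2", "MAF", "BETA"]].to_string(index=False))
print(
    "\nrs1's duplicate was dropped at read time; rs2 is strand-ambiguous "
    "(A/T), rs3 sits in the APOE block, and rs5 fails the INFO > 0.9 filter. "
    "rs4's alleles were reported reversed, so its log-odds changed sign."
)
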