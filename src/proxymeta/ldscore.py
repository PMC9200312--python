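"""LD-score tables: per-SNP LD scores plus the reference-panel SNP count M.

The regression denominator M is the number of SNPs in the reference panel
*before* excluding the MHC/APOE regions, so heritability estimates keep their
usual genome-wide interpretation; the table itself may contain fewer rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class LDScoreTable:
    """Per-SNP LD scores (columns ``SNP CHR BP L2``) and the panel count M."""

    df: pd.DataFrame
    m: float  # denominator entered in the LDSC slope conversion (pre-exclusion)
    m_post: float | None = field(default=None)  # rows surviving region exclusion

    def __post_init__(self) -> None:
        for col in ("SNP", "L2"):
            if col not in self.df.columns:
                raise ValueError(f"LD-score table missing column {col}")
        if self.m_post is None:
            self.m_post = float(len(self.df))
        if self.m <= 0:
            raise ValueError("M must be positive")


def load_ldscores(path) -> LDScoreTable:
    """Read a tab-delimited LD-score file with a companion ``<path>.M`` count.

    The ``.M`` file holds one or two whitespace-separated numbers: the
    pre-exclusion panel count and optionally the post-exclusion count.  Without
    a companion file M defaults to the number of table rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns=str.upper)
    m_file = path.with_name(path.name + ".M")
    if m_file.exists():
        parts = m_file.read_text().split()
        m = float(parts[0])
        m_post = float(parts[1]) if len(parts) > 1 else None
    else:
        m, m_post = float(len(df)), None
    return LDScoreTable(df=df, m=m, m_post=m_post)


def save_ldscores(ld: LDScoreTable, path) -> None:
    path = Path(path)
    cols = [c for c in ("SNP", "CHR", "BP", "L2") if c in ld.df.columns]
    ld.df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")
    path.with_name(path.name + ".M").write_text(f"{ld.m:g} {ld.m_post:g}\n")
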