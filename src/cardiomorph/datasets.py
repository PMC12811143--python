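"""Bundled genotype incidence tables for the two genetic-interaction crosses.

Membranous-VSD counts per genotype group for the Tbx5 x Slit2 and
Tbx5 x Ntn1 experiments. The wild-type control group is entered as 0
affected of 14 — controls are reported without any VSD — and this
assumption is an explicit input here, not hidden inside the fitting code.
Alternative plausible group sets (for sensitivity analysis of the ambiguous
group composition) are provided alongside the defaults.
"""

from __future__ import annotations

import pandas as pd


def _table(rows: list[tuple[str, int, int, int, int]]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["genotype_label", "tbx5_dose", "gene_dose", "affected", "total"],
    )


def slit2_membranous_counts() -> pd.DataFrame:
    """Membranous-VSD incidence for the Tbx5 x Slit2 cross (default group set)."""
    return _table(
        [
            ("WT", 0, 0, 0, 14),
            ("Tbx5_het", 1, 0, 5, 8),
            ("Slit2_het", 0, 1, 1, 8),
            ("Slit2_hom", 0, 2, 3, 4),
            ("Tbx5_het;Slit2_het", 1, 1, 5, 8),
        ]
    )


def ntn1_membranous_counts() -> pd.DataFrame:
    """Membranous-VSD incidence for the Tbx5 x Ntn1 cross (default group set)."""
    return _table(
        [
            ("WT", 0, 0, 0, 14),
            ("Tbx5_het", 1, 0, 5, 8),
            ("Ntn1_het", 0, 1, 1, 9),
            ("Ntn1_hom", 0, 2, 6, 7),
            ("Tbx5_het;Ntn1_het", 1, 1, 1, 8),
        ]
    )


def sensitivity_group_sets(gene: str) -> dict[str, pd.DataFrame]:
    """Plausible alternative group sets for the stated cross.

    Variants cover the ambiguities in group composition: excluding the
    homozygous group from the interaction fit, and the alternatively
    reported Tbx5 heterozygote denominator (5 of 7 instead of 5 of 8).
    """
    if gene == "slit2":
        default = slit2_membranous_counts()
    elif gene == "ntn1":
        default = ntn1_membranous_counts()
    else:
        raise ValueError("gene must be 'slit2' or 'ntn1'")
    no_hom = default[default["gene_dose"] != 2].reset_index(drop=True)
    alt_tbx5 = default.copy()
    alt_tbx5.loc[alt_tbx5["genotype_label"] == "Tbx5_het", "total"] = 7
    return {"default": default, "without_homozygotes": no_hom, "tbx5_het_5_of_7": alt_tbx5}
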