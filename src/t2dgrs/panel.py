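"""Published type 2 diabetes SNP panel used as reference input.

The packaged table ``data/ckb_agen_t2d_panel.tsv`` transcribes published
per-SNP summary statistics for 56 established type 2 diabetes risk variants:
risk-allele frequencies in a Chinese population-based cohort (CKB) and
reference panels, per-allele odds ratios with 95% CIs from CKB and from the
East Asian AGEN-T2D case-control meta-analysis, the published fixed-effect
pooled values, and heterogeneity p-values.

The ``mechanism`` column (beta-cell dysfunction vs insulin resistance) is an
illustrative assignment from standard locus biology used to parameterise the
synthetic cohort; the original per-SNP evidence table is supplementary
material and not reproduced here.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_PANEL_CACHE: pd.DataFrame | None = None


def load_panel() -> pd.DataFrame:
    """Return the packaged 56-SNP summary-statistics table."""
    global _PANEL_CACHE
    if _PANEL_CACHE is None:
        with resources.files("t2dgrs.data").joinpath("ckb_agen_t2d_panel.tsv").open() as fh:
            _PANEL_CACHE = pd.read_csv(fh, sep="\t")
    return _PANEL_CACHE.copy()


def study_estimates(study: str = "ckb") -> pd.DataFrame:
    """Per-SNP (or, lo, hi, p) for one study column: 'ckb', 'agen' or 'meta'."""
    if study not in ("ckb", "agen", "meta"):
        raise ValueError(f"unknown study {study!r}")
    df = load_panel()
    out = df[["snp_id", "gene", f"or_{study}", f"lo_{study}", f"hi_{study}", f"p_{study}"]]
    out = out.rename(columns={f"or_{study}": "or_", f"lo_{study}": "ci_low",
                              f"hi_{study}": "ci_high", f"p_{study}": "p"})
    return out.dropna(subset=["or_"]).reset_index(drop=True)


def default_snp_specs(subset: str = "grs", missing_rate: float = 0.0):
    """Build SnpSpec objects for the synthetic cohort from the panel.

    True per-allele log odds ratios are taken from the population-based (CKB)
    column so the simulated effect-size spectrum matches the study: ORs
    roughly 0.9-1.4 with most between 1.0 and 1.3.

    subset: 'grs' (the 52 score variants), 'all' (56), 'bc' or 'ir'.
    """
    from .simulate import SnpSpec  # deferred: avoid import cycle

    df = load_panel()
    if subset == "grs":
        df = df[df.in_grs == 1]
    elif subset in ("bc", "ir"):
        df = df[(df.in_grs == 1) & (df.mechanism == subset.upper())]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    return [
        SnpSpec(snp_id=r.snp_id, raf=float(r.raf_ckb),
                beta_true=float(np.log(r.or_ckb)), mechanism=r.mechanism,
                missing_rate=missing_rate)
        for r in df.itertuples()
    ]


def mechanism_members(mechanism: str) -> list[str]:
    """SNP ids of the illustrative beta-cell ('BC') or IR ('IR') subsets."""
    df = load_panel()
    return df.loc[(df.in_grs == 1) & (df.mechanism == mechanism), "snp_id"].tolist()
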