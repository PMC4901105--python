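"""Fixed-effect meta-analysis of the packaged two-study summary table.

Recovers study standard errors from the printed 95% CIs, pools the
population-based cohort (CKB) and East Asian consortium (AGEN-T2D)
estimates per SNP by inverse-variance fixed effects, computes Cochran's Q
heterogeneity, and checks the pooled odds ratios against the published
pooled column (agreement to +/-0.01 is expected given CI rounding).
"""
import numpy as np

from _common import outdir

from t2dgrs import panel
from t2dgrs.meta import HETEROGENEITY_ALPHA, pool_summary_frame


def main():
    df = panel.load_panel().dropna(subset=["or_agen"])
    pooled = pool_summary_frame({
        "ckb": panel.study_estimates("ckb"),
        "agen": panel.study_estimates("agen"),
    }).set_index("snp_id")
    published = df.set_index("snp_id")[["gene", "or_meta", "p_het"]]
    published = published.rename(columns={"p_het": "p_het_published"})
    merged = pooled.join(published)
    merged["abs_diff_vs_published"] = (merged.or_ - merged.or_meta).abs()
    out = outdir("meta")
    merged.reset_index().to_csv(out / "meta_analysis.tsv", sep="\t", index=False)

    worst = merged.abs_diff_vs_published.max()
    print(f"pooled {len(merged)} SNPs; max |pooled OR - published| = {worst:.4f}")
    het = merged[merged.p_het < HETEROGENEITY_ALPHA]
    print(f"SNPs with Bonferroni-significant heterogeneity "
          f"(p < {HETEROGENEITY_ALPHA:.1e}): "
          f"{', '.join(het.gene.tolist()) or 'none'}")
    top = merged.nsmallest(3, "p")[["gene", "or_", "p"]]
    for g, o, p in top.itertuples(index=False):
        print(f"  strongest signals: {g}: OR {o:.2f}, p = {p:.2e}")
    print(f"wrote {out}/meta_analysis.tsv")


if __name__ == "__main__":
    main()
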