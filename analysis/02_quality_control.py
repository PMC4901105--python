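"""Quality control of the simulated cohort.

Applies the per-SNP filters (call rate >= 95%, Hardy-Weinberg p >= 1.3e-4)
and per-sample filters (call rate >= 98%, robust heterozygosity-F |z| < 5)
and writes the QC reports. On clean simulated data essentially everything
should pass; the script prints the in/out record counts.
"""
from _common import DEFAULT_SEED, outdir, study_cohort

from t2dgrs.qc import sample_qc, snp_qc


def main(seed: int = DEFAULT_SEED):
    cohort = study_cohort(seed)
    G = cohort.genotypes
    srep = snp_qc(G)
    prep = sample_qc(G)
    out = outdir("qc")
    srep.to_csv(out / "snp_qc.tsv", sep="\t", index=False)
    prep.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    print(f"SNPs kept: {int(srep.kept.sum())}/{len(srep)}")
    print(f"samples kept: {int(prep.kept.sum())}/{len(prep)}")
    print(f"median sample call rate: {prep.call_rate.median():.4f}")
    print(f"wrote {out}/snp_qc.tsv and {out}/sample_qc.tsv")


if __name__ == "__main__":
    main()
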