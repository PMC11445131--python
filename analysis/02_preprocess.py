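"""Filter genes, quantile-normalize, and split into the six strata.

Applies the protocol's two gene filters (mean count >= 10; zero counts
in at most half the samples) on the full cohort, normalizes all samples
onto one reference distribution, then writes one expression matrix per
sex x age stratum.
"""

from coexpnet import FilterConfig, filter_genes, load_dataset, quantile_normalize, split_groups
from coexpnet.simulate import STRATA

from config import RESULTS


def main() -> None:
    data = RESULTS / "data"
    outdir = RESULTS / "strata"
    outdir.mkdir(parents=True, exist_ok=True)

    counts, meta = load_dataset(data / "counts.tsv", data / "metadata.tsv")
    filtered = filter_genes(counts, FilterConfig())
    normalized = quantile_normalize(filtered)
    strata = split_groups(normalized, meta)

    for label in STRATA:
        strata[label].to_csv(outdir / f"{label}.tsv", sep="\t",
                             index_label="gene_id", float_format="%.10g")
    (outdir / "universe.txt").write_text("\n".join(filtered.index) + "\n")

    print(f"genes: {counts.shape[0]} in, {filtered.shape[0]} pass the filters")
    print("stratum sample counts: "
          + ", ".join(f"{s}={strata[s].shape[1]}" for s in STRATA))


if __name__ == "__main__":
    main()
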