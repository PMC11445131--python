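"""Over-representation of unique-subnetwork genes in the planted modules.

Uses the module-derived GMT as the gene-set library and the filtered
gene universe.  A stratum's unique interactions should over-represent
the module planted specifically in that stratum — the synthetic analog
of unique transcriptional programs enriching distinct biological
processes.
"""

from coexpnet import Network, read_gmt, unique_edges
from coexpnet.enrich import enrich, membership_frame, process_membership, results_frame
from coexpnet.simulate import STRATA

from config import FDR, RESULTS


def main() -> None:
    outdir = RESULTS / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    collection = read_gmt(RESULTS / "data" / "modules.gmt")
    universe = {line.strip() for line
                in (RESULTS / "strata" / "universe.txt").read_text().splitlines()
                if line.strip()}
    networks = {s: Network.read_tsv(RESULTS / "networks" / f"{s}.tsv", name=s)
                for s in STRATA}

    significant = {}
    for label in STRATA:
        uniq = unique_edges(networks[label],
                            [networks[s] for s in STRATA if s != label])
        results = enrich(uniq.genes, collection, universe, threshold=FDR)
        results_frame(results).to_csv(outdir / f"{label}.csv", index=False)
        hits = [r for r in results if r.significant]
        significant[label] = {r.term for r in hits}
        print(f"{label}: {len(uniq.genes)} unique-subnetwork genes; "
              f"{len(hits)} module(s) over-represented at FDR<{FDR}: "
              + (", ".join(f"{r.term} (q={r.p_adj:.2g})" for r in hits) or "none"))

    membership, combos = process_membership(significant)
    membership_frame(membership).to_csv(outdir / "process_membership.csv", index=False)
    shared_all = [t for t, nets in membership.items() if len(nets) == len(STRATA)]
    print(f"terms significant in all six networks: {len(shared_all)}")


if __name__ == "__main__":
    main()
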