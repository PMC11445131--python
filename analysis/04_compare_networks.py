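"""Compare the six networks: shared, conserved and unique structure.

Computes pairwise shared-edge and shared-gene matrices (counts and
Jaccard), the interactions conserved within men, within women, and
across all six networks, and each stratum's unique-interaction
subnetwork with its component statistics.
"""

import json

import pandas as pd

from coexpnet import Network, components, conserved_edges, pairwise_overlap, unique_edges
from coexpnet.simulate import STRATA

from config import RESULTS


def main() -> None:
    outdir = RESULTS / "comparison"
    outdir.mkdir(parents=True, exist_ok=True)
    networks = {s: Network.read_tsv(RESULTS / "networks" / f"{s}.tsv", name=s)
                for s in STRATA}
    nets = [networks[s] for s in STRATA]

    for mode in ("edges", "genes"):
        overlap = pairwise_overlap(nets, mode=mode)
        overlap.counts_frame().to_csv(outdir / f"overlap_{mode}_counts.csv")
        overlap.jaccard_frame().to_csv(outdir / f"overlap_{mode}_jaccard.csv")

    conserved = {
        "men": conserved_edges([networks[s] for s in ("MY", "MM", "ME")], "conserved_men"),
        "women": conserved_edges([networks[s] for s in ("FY", "FM", "FE")], "conserved_women"),
        "all": conserved_edges(nets, "conserved_all"),
    }
    for label, net in conserved.items():
        net.write_tsv(outdir / f"conserved_{label}.tsv")
    print("conserved interactions: "
          + ", ".join(f"{k}={len(v)}" for k, v in conserved.items()))

    rows = []
    comp_payload = {}
    for label in STRATA:
        uniq = unique_edges(networks[label],
                            [networks[s] for s in STRATA if s != label])
        uniq.write_tsv(outdir / f"unique_{label}.tsv")
        summary = components(uniq)
        rows.append({"network": label, "unique_edges": len(uniq),
                     "unique_genes": len(uniq.genes),
                     "lcc_genes": summary.lcc_genes,
                     "n_components": summary.n_components})
        comp_payload[label] = summary.to_dict()
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "unique_summary.csv", index=False)
    (outdir / "unique_components.json").write_text(json.dumps(comp_payload, indent=1))
    print("unique-interaction subnetworks (edges / genes / LCC):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
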