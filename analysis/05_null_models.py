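"""Bootstrap significance of each unique subnetwork's largest component.

For each stratum: draw random edge subsets of the unique-interaction
size from that stratum's full network, compute the largest-connected-
component gene count per draw, and compare the observed unique-LCC to
this null.  A small upper-tail p means the unique transcriptional
program is more connected than chance; a small lower tail means it is
more fragmented.
"""

import argparse
import json

from coexpnet import Network, components, lcc_null_test, unique_edges
from coexpnet.pipeline import derive_seed
from coexpnet.simulate import STRATA

from config import N_SIMS, RESULTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--nsims", type=int, default=N_SIMS)
    args = parser.parse_args()

    outdir = RESULTS / "nulls"
    outdir.mkdir(parents=True, exist_ok=True)
    networks = {s: Network.read_tsv(RESULTS / "networks" / f"{s}.tsv", name=s)
                for s in STRATA}

    for label in STRATA:
        uniq = unique_edges(networks[label],
                            [networks[s] for s in STRATA if s != label])
        observed = components(uniq).lcc_genes
        result = lcc_null_test(
            networks[label], subset_size=len(uniq), observed_lcc=observed,
            n_sims=args.nsims, seed=derive_seed(args.seed, "null", label),
        )
        result.to_json(outdir / f"{label}.json")
        direction = ("larger" if result.p_ge < result.p_le
                     else "smaller" if result.p_le < result.p_ge else "as")
        print(f"{label}: observed LCC {observed} vs null "
              f"{result.null_mean:.1f} +/- {result.null_sd:.1f} "
              f"({direction} than chance; p_ge={result.p_ge:.2g}, "
              f"p_le={result.p_le:.2g})")


if __name__ == "__main__":
    main()
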