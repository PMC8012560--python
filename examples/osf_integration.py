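"""Optional integration check against the deposited empirical dataset.

The empirically estimated 27-item checklist results (the baseline
ESA around 5.3 with SAS around 0.27 from 1,000-iteration chains, the
symptom-subnetwork density of 0.55, and the conditioned ESA values
36.21 / 35.45 / 36.70) were computed from a public study deposit at
https://osf.io/jhzk3/ that this package does not download.  Chain-based
values additionally depend on an unreported chain seed, so agreement is
a qualitative band, not an exact match.

To run the check yourself, download the item-level CSV from the deposit
and point this script at it.  Nothing in the automated test suite
depends on this file.
"""

import sys

import pandas as pd

import netresil as nr


def main(path: str) -> None:
    raw = pd.read_csv(path)
    scl = raw[[c for c in raw.columns if c.upper().startswith("SCL")]]
    binary = nr.binarize(scl)  # {0,1,2} -> 0, {3,4} -> 1
    net = nr.fit_elasso(binary.data)
    print(f"estimated {net.n_nodes}-node network, density {nr.density(net):.2f}")
    table = nr.node_strength(net)
    print("five strongest nodes:", nr.select_extreme_nodes(table, 5, "strongest"))

    rep = nr.chain_resilience(net, nr.ChainConfig(iterations=1000, seed=0))
    print(f"chain baseline (1,000 iterations): ESA={rep.esa:.2f} SAS={rep.sas:.2f}")
    print("expected band: ESA near 5.3, SAS near 0.27 (chain-seed dependent)")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit("usage: python examples/osf_integration.py <scl_items.csv>")
    main(sys.argv[1])
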