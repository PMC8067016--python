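#!/usr/bin/env python
"""Chitinase catalytic-motif scan on simulated proteins.

Plants the conserved DXXDXDXE catalytic motif in half of a simulated
protein set and verifies the wildcard scanner recovers every planted
position (spurious background matches are possible and are reported
separately).
"""

from pathlib import Path

import pandas as pd

from bdellocomp import scan_motif, simulate_proteins
from bdellocomp.io import write_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_proteins(100, motif_rate=0.5, seed=13)
    matches = scan_motif(records)
    found = {(m.protein_id, m.start) for m in matches}
    planted = set(truth)
    recovered = planted & found
    spurious = found - planted
    write_tsv(
        pd.DataFrame(
            [
                {"protein_id": m.protein_id, "start": m.start, "end": m.end,
                 "matched": m.matched,
                 "planted": (m.protein_id, m.start) in planted}
                for m in matches
            ],
            columns=["protein_id", "start", "end", "matched", "planted"],
        ),
        OUT / "motif_scan.tsv",
    )
    print(f"planted motifs: {len(planted)}; recovered: {len(recovered)} "
          f"({100.0 * len(recovered) / len(planted):.0f}%)")
    print(f"background (unplanted) matches: {len(spurious)}")
    assert recovered == planted, "scanner missed a planted motif"


if __name__ == "__main__":
    main()
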