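#!/usr/bin/env python
"""Materialize the worked-example genome collections under results/fixtures/.

These four small collections encode the study's headline counts (marine
enrichment carriers, environment sources, cheB carriers, shared peptidase
families) and are the inputs to the downstream comparison drivers.
"""

from pathlib import Path

from bdellocomp import make_fixture
from bdellocomp.synthetic_data import FIXTURE_NAMES

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    for name in FIXTURE_NAMES:
        bundle = make_fixture(name)
        paths = bundle.write(OUT)
        print(f"{name}: {len(bundle.metadata)} genomes, "
              f"{len(bundle.annotations)} annotation rows")
        print(f"  note: {bundle.notes}")
        for kind, path in paths.items():
            print(f"  {kind}: {path.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
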