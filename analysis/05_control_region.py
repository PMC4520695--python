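#!/usr/bin/env python
"""Control-region element scan across the synthetic panel.

Scans each genome's control region for the five conserved elements (poly-T,
[TA]n tract, stem-loop with TATA / G(A)nT flanks, G+A-rich domain), checks
the conserved order, and counts TA repeats. Writes results/control_region.json.
"""

import dataclasses
import json
from pathlib import Path

from midgemito.control_region import count_cr_repeats, scan_control_region
from midgemito.model import extract_feature_sequence
from midgemito.simulate import generate_biotype_panel

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    results = {}
    all_five = 0
    for record, truth in generate_biotype_panel(1):
        cr = str(extract_feature_sequence(record, record.feature("CR")))
        ann = scan_control_region(cr)
        reps = count_cr_repeats(cr)
        found = ann.found_elements()
        all_five += len(found) == 6      # five elements + the scanner's 5'/3' split
        results[truth["biotype"]] = {
            "length": len(cr),
            "elements_found": found,
            "order_conserved": ann.order_conserved,
            "stem_loop": dataclasses.asdict(ann.stem_loop) if ann.stem_loop else None,
            "ta_copies": reps["ta_copies"],
        }
        print(f"{truth['biotype']:>10}: {len(found)} elements, "
              f"order conserved: {ann.order_conserved}, "
              f"stem-loop span {ann.stem_loop.span[1] - ann.stem_loop.span[0]} bp, "
              f"TA x{reps['ta_copies']}")
    (OUT / "control_region.json").write_text(json.dumps(results, indent=2))
    print(f"\nall elements present and ordered in {all_five}/9 genomes "
          f"(published: all five elements in conserved order, 42 bp stem loops)")


if __name__ == "__main__":
    main()
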