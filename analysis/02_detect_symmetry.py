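#!/usr/bin/env python
"""Detect the cyclic order of each planted tier map by rotational power
spectrum and tabulate the result.

Reads the fixtures from 01_generate_fixtures.py and writes
results/symmetry_detection.csv plus the full spectra as JSON.  The finding
to look for: every tier's detected fold equals its planted order (23, 11,
34) despite SNR-1 noise at 8.6 Å.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from msring.density import detect_symmetry, read_map
from msring.geometry import SymmetryAxis

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "results" / "fixtures"
Z_AXIS = SymmetryAxis(np.zeros(3), np.array([0.0, 0.0, 1.0]))


def main() -> None:
    truth = json.loads((FIXTURES / "ground_truth.json").read_text())
    rows = []
    spectra = {}
    for name, info in truth["planted"].items():
        order, radius = info["order"], info["radius_A"]
        dmap = read_map(FIXTURES / f"map_{name}_c{order}.mrc")
        det = detect_symmetry(
            dmap, Z_AXIS, (radius - 15.0, radius + 15.0, -12.0, 12.0),
            candidates=range(2, 41), n_max=40,
        )
        rows.append(
            {
                "tier": name,
                "planted_order": order,
                "detected_fold": det.best_fold,
                "confidence": round(det.confidence, 2),
                "ambiguous": det.ambiguous,
            }
        )
        spectra[name] = det.spectrum.to_dict()
        print(
            f"{name}: planted C{order} -> detected C{det.best_fold} "
            f"(confidence {det.confidence:.1f}{', AMBIGUOUS' if det.ambiguous else ''})"
        )
    table = pd.DataFrame(rows)
    out_csv = ROOT / "results" / "symmetry_detection.csv"
    table.to_csv(out_csv, index=False)
    (ROOT / "results" / "rotational_spectra.json").write_text(json.dumps(spectra, indent=1))
    assert (table.planted_order == table.detected_fold).all(), "a planted order was missed"
    print(f"all planted orders recovered; table at {out_csv}")


if __name__ == "__main__":
    main()
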