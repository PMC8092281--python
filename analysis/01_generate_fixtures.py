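#!/usr/bin/env python
"""Generate the synthetic study inputs: toy subunit, template double ring,
and planted tier maps (C23 inner, C11 middle, C34 S-ring) with SNR-1 noise.

Writes mmCIF models, MRC maps and a ground-truth JSON under
results/fixtures/.  Everything is derived from one seed and is
bit-reproducible.
"""

import json
from pathlib import Path

from msring.density import write_map
from msring.model import write_structure
from msring.synthetic import (
    ToySubunitSpec,
    make_homolog_template_rings,
    make_planted_ring_map,
    make_toy_subunit,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subunit = make_toy_subunit(ToySubunitSpec(seed=SEED))
    write_structure(subunit, OUT / "subunit.cif")
    t_in, t_out = make_homolog_template_rings(seed=SEED, subunit=subunit)
    t_in.save(OUT / "template_inner.cif")
    t_out.save(OUT / "template_outer.cif")

    truth = {"seed": SEED, "planted": {}}
    for name, order, radius in (("inner", 23, 62.0), ("middle", 11, 70.0), ("sring", 34, 85.0)):
        ring, dmap = make_planted_ring_map(
            subunit, order, radius, resolution=8.6, noise_snr=1.0, seed=SEED,
            tier_name=name,
        )
        write_map(dmap, OUT / f"map_{name}_c{order}.mrc")
        ring.save(OUT / f"ring_{name}_c{order}.cif")
        truth["planted"][name] = {"order": order, "radius_A": radius, "grid": list(dmap.shape)}
        print(f"{name}: planted C{order} at {radius} Å, map grid {dmap.shape}")
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
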