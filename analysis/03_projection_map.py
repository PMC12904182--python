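#!/usr/bin/env python
"""Per-residue projection map of the intermediates onto the
closed→desensitized axis (the heatmap/line-graph view of the transition).

Each intermediate's C-α is projected onto the line from its closed-state to
its desensitized-state position; the fraction (0 = closed, 1 =
desensitized) is tabulated residues × models in
results/projection_matrix.tsv with per-domain means appended. For the
λ-interpolated intermediates every defined fraction equals λ up to PDB
coordinate rounding.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from plgic.structures import (build_correspondence,             # noqa: E402
                              read_structure, write_table)
from plgic.synth import default_config                          # noqa: E402
from plgic.transitions import (export_projection_matrix,        # noqa: E402
                               projection_profile)


def main():
    states = ROOT / "scratch" / "states"
    if not (states / "closed.pdb").exists():
        sys.exit("run analysis/01_simulate_states.py first")
    cfg = default_config()
    closed = cfg.annotate(read_structure(states / "closed.pdb"))
    desens = cfg.annotate(read_structure(states / "desensitized.pdb"))
    corr_cd = build_correspondence(closed, desens)

    profiles = []
    for path in sorted(states.glob("intermediate_*.pdb")) + \
            [states / "desensitized.pdb"]:
        query = cfg.annotate(read_structure(path))
        prof = projection_profile(closed, desens, query, corr_cd,
                                  build_correspondence(closed, query))
        prof.query_label = path.stem
        profiles.append(prof)
        fr = [r["fraction"] for r in prof.records if r["defined"]]
        print(f"{path.stem:22s} mean fraction {np.mean(fr):.3f} "
              f"({len(fr)} defined residues), domain means "
              + ", ".join(f"{d}={v:.3f}"
                          for d, v in sorted(prof.domain_means.items())
                          if d in ("ECD", "TMD")))
    write_table(export_projection_matrix(profiles),
                ROOT / "results" / "projection_matrix.tsv")


if __name__ == "__main__":
    main()
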