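"""Conformational landscape and state kinetics of the oxyanion-strand toy.

Samples an unbiased overdamped Langevin trajectory on the calibrated
three-basin dihedral potential, classifies every frame into the
inactive/unblocked/active oxyanion-strand states, and writes state
populations, dwell segments, the transition count matrix and the
population free-energy landscape under results/.
"""
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from allostate import fel, states, synthdata as sd, trajio
from allostate._util import kt_kcal

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    t0 = time.time()
    RESULTS.mkdir(exist_ok=True)
    pot = sd.make_triple_well()
    print("triple-well barriers (kT at 300 K):",
          {k: round(v / kt_kcal(300.0), 3)
           for k, v in pot.true_barriers.items()
           if k[0] == "inactive"})

    params = sd.LangevinParams(n_steps=400_000, dt=0.002, diffusion=2000.0,
                               seed=SEED, x0=(-130.0, -70.0))
    series = sd.langevin_sample(pot, params)
    trajio.write_colvar(series, RESULTS / "01_langevin.colvar")

    st = states.classify_states(series.column("phi_v51"),
                                series.column("phi_g50"),
                                times=series.times)
    pops = st.populations()
    pops.to_csv(RESULTS / "01_state_populations.csv",
                header=["population"])
    print("state populations:")
    print(pops.to_string())

    dw = states.dwell_segments(st.labels, min_dwell_frames=50,
                               times=series.times)
    dw.transitions.to_csv(RESULTS / "01_transition_counts.csv")
    seg = pd.DataFrame(dw.segments,
                       columns=["state", "start", "end", "duration_ns"])
    seg.to_csv(RESULTS / "01_dwell_segments.csv", index=False)
    n_inter = int(dw.transitions.to_numpy().sum())
    print(f"{len(seg)} dwell segments, {n_inter} interconversions "
          f"over {series.times[-1]:.0f} ns")

    grid = fel.landscape_from_samples(
        series.values, fel.GridSpec.dihedral(pot.cv_names, 72))
    grid.to_frame().to_csv(RESULTS / "01_population_fel.csv", index=False)
    visited = (~grid.mask).mean()
    print(f"population FEL: {visited * 100:.0f}% of bins visited; "
          f"max F {np.nanmax(grid.values):.2f} kcal/mol")
    print(f"done in {time.time() - t0:.0f}s")


if __name__ == "__main__":
    main()
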