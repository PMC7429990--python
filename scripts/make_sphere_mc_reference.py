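"""Regenerate the frozen Monte-Carlo sphere reference fixture.

Runs the reflecting-sphere random walk (1e5 walkers) for a rectangular PGSE
carrying b = 5 ms/um^2 over the (radius, diffusivity) grid and writes
tests/data/sphere_mc_reference.json after each condition.

The specular-reflection walk carries a signal bias that is first order in
the RMS step length.  For the r = 5 um cells — where the Gaussian-phase
signal sits closest to the 2% comparison band — the reference is therefore
the Richardson extrapolation to zero step of a 0.025 um and a 0.05 um run
(``2 * fine - coarse``); the remaining cells use a single 0.035 um run,
comfortably inside their margins.  All steps respect the 0.05 um accuracy
ceiling.  Takes several CPU-hours; the test suite only reads the frozen
output.
"""

import json
import math
import time
from pathlib import Path

import stedot as st
from stedot.montecarlo import random_walk_sphere_signal

GAMMA_UM = 267.513e-6
DELTA, SEPARATION, B = 1.0, 30.0, 5.0
N_WALKERS = 100_000
SEED = 20260
OUT = Path(__file__).resolve().parent.parent / "tests" / "data" / "sphere_mc_reference.json"

# (radius um, D um^2/ms, fine step um, coarse step um or None),
# tightest comparisons first
CONDITIONS = [
    (5.0, 3.0, 0.025, 0.05),
    (5.0, 1.0, 0.025, 0.05),
    (10.0, 3.0, 0.035, None),
    (10.0, 1.0, 0.035, None),
    (2.0, 3.0, 0.035, None),
    (2.0, 1.0, 0.035, None),
]


def main():
    amplitude = math.sqrt(B / (SEPARATION - DELTA / 3.0)) / (GAMMA_UM * DELTA)
    w = st.make_pgse_waveform(amplitude, DELTA, SEPARATION, dt=0.02)
    assert abs(st.btensor_from_waveform(w).b - B) < 1e-9
    doc = {
        "waveform": {
            "amplitude_mT_m": amplitude,
            "delta_ms": DELTA,
            "separation_ms": SEPARATION,
            "dt_ms": 0.02,
            "b_ms_um2": B,
        },
        "conditions": [],
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    for r, d, fine, coarse in CONDITIONS:
        t0 = time.time()
        mc_fine = random_walk_sphere_signal(
            w, r, d, n_walkers=N_WALKERS, max_step=fine, seed=SEED
        )
        cond = {
            "radius_um": r,
            "d_intra_um2_ms": d,
            "n_walkers": N_WALKERS,
            "seed": SEED,
            "max_step_um": fine,
            "mc_fine": mc_fine,
        }
        if coarse is not None:
            mc_coarse = random_walk_sphere_signal(
                w, r, d, n_walkers=N_WALKERS, max_step=coarse, seed=SEED + 1
            )
            cond["coarse_step_um"] = coarse
            cond["coarse_seed"] = SEED + 1
            cond["mc_coarse"] = mc_coarse
            cond["mc_signal"] = 2.0 * mc_fine - mc_coarse  # step -> 0 limit
        else:
            cond["mc_signal"] = mc_fine
        print(
            f"r={r} D={d}: mc_signal={cond['mc_signal']:.5f} "
            f"({time.time() - t0:.0f}s)",
            flush=True,
        )
        doc["conditions"].append(cond)
        with open(OUT, "w") as fh:
            json.dump(doc, fh, indent=1)
        print(f"updated {OUT} ({len(doc['conditions'])} conditions)", flush=True)


if __name__ == "__main__":
    main()
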