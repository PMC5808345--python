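"""Regenerate the packaged control 1 Hz paced steady-state snapshot.

Usage:  python scripts/bootstrap_steady_state.py [--duration 260]

Paces the control model at 1 Hz from a cold start, verifies cycle-to-cycle
convergence, and writes src/ipsccm/data/steady_state_1hz.json together with
the stimulus threshold measured at that state.
"""

import argparse
import json
import pathlib

from ipsccm import Model, StimulusSpec, find_threshold, run_to_steady_state

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "ipsccm" / "data" / "steady_state_1hz.json"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--duration", type=float, default=260.0, help="pacing time, s")
    args = ap.parse_args()

    model = Model()
    res = run_to_steady_state(model, StimulusSpec(mode="paced", frequency=1.0),
                              duration=args.duration)
    print(f"converged={res.converged} apd90_spread={res.apd90_spread:.2e} "
          f"cat_spread={res.cat_spread:.2e}")
    thr = find_threshold(model, y0=res.state)
    print(f"threshold at steady state: {thr:.3f} pA/pF")
    snap = {
        "params_hash": model.params_hash(),
        "n_shells": model.grid.n_shells,
        "cell_radius": model.grid.cell_radius,
        "pacing_hz": 1.0,
        "duration_s": args.duration,
        "converged": bool(res.converged),
        "threshold": thr,
        "y": [float(v) for v in res.state],
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(snap))
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
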