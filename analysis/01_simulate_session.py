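"""Generate the study's synthetic session and store it in the tabular layout.

The population mirrors the structure of the recorded sample: a subset of cells
with a strong large-reward Cspk cue transient (weakly positive in the rest),
~40% directionally tuned with anti-phase Cspk/Sspk preferred directions,
heterogeneous Sspk cue responses, and reward-invariant direction tuning.
"""

from _common import RESULTS, SEED, SESSION_DIR

from pursuitcspk.data_model import write_session
from pursuitcspk.synthetic import paper_like_config, simulate_session


def main():
    session = simulate_session(paper_like_config(n_cells=40, n_trials=15, master_seed=SEED))
    write_session(session, SESSION_DIR, format="tabular")
    n_success = sum(t.success for t in session.trials)
    print(f"wrote {SESSION_DIR}")
    print(f"  trials: {len(session.trials)} ({n_success} successful)")
    print(f"  cells: {len(session.cells)}")
    print(f"  duration: {session.eye.time[-1] / 1000.0:.0f} s")
    print(f"  licks: {len(session.licks)}, ground-truth saccades: {len(session.saccades)}")


if __name__ == "__main__":
    main()
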