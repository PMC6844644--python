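"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

from pursuitcspk.data_model import read_session
from pursuitcspk.synthetic import paper_like_config, simulate_session

RESULTS = Path(__file__).resolve().parent.parent / "results"
SESSION_DIR = RESULTS / "session"
SEED = 0


def get_session():
    """The study session: read the stored layout if 01 ran, else regenerate it."""
    if (SESSION_DIR / "trials.csv").exists():
        return read_session(SESSION_DIR, format="tabular")
    return simulate_session(paper_like_config(n_cells=40, n_trials=15, master_seed=SEED))
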