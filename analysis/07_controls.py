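"""Controls: lick contribution to the cue response, and the Cspk-triggered CCG.

The lick control builds a lick-onset PETH per cell (conditions pooled), tiles
it around every lick, and averages the resulting synthetic rate traces per
reward condition aligned to the cue: if licking drove the cue response, this
prediction would reproduce it.  The cross-correlogram shows the simple-spike
pause after each complex spike (with the [-1,+2] ms spikelet blank window).
"""

import numpy as np
import pandas as pd
from _common import RESULTS, get_session

from pursuitcspk.data_model import AnalysisParams, select_trials
from pursuitcspk.spiketrains import cspk_triggered_ccg, event_contribution_psth, peth, psth

P = AnalysisParams()


def main():
    session = get_session()
    trials = select_trials(session)
    lick_onsets = session.licks[:, 0]

    # assign licks to trials for the per-trial reconstruction
    events = {}
    for tr in trials:
        lo, hi = tr.start(session.task), tr.end(session.task)
        events[tr.trial_id] = [int(x) for x in lick_onsets if lo <= x < hi]

    cell = session.cells[0]
    pe = peth(cell.cspk, lick_onsets, P.peth_halfwidth, P)
    pred = event_contribution_psth(trials, events, pe, "cue", (-400, 800), P)
    obs = {
        cond: psth(cell.cspk, [t.cue_onset for t in trials if t.reward == cond], (-400, 800), P)
        for cond in ("large", "small")
    }
    print(f"lick-contribution control ({cell.cell_id}):")
    for cond in ("large", "small"):
        sel = (obs[cond].time >= 100) & (obs[cond].time < 300)
        print(f"  {cond}: observed cue-window rate {obs[cond].rate[sel].mean():.2f} sp/s, "
              f"lick-predicted {np.nanmean(pred[cond].rate[sel]):.2f} sp/s")
    out = pd.DataFrame({
        "t_ms": obs["large"].time,
        "observed_large": obs["large"].rate,
        "observed_small": obs["small"].rate,
        "predicted_large": pred["large"].rate,
        "predicted_small": pred["small"].rate,
    })
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "lick_contribution.csv", index=False)

    bounds = [(t.start(session.task), t.end(session.task)) for t in session.trials]
    ccg = cspk_triggered_ccg(cell.cspk, cell.sspk, bounds, 100, P)
    pd.DataFrame({"lag_ms": ccg.time, "rate": ccg.rate}).to_csv(
        RESULTS / "ccg.csv", index=False
    )
    pause = ccg.rate[(ccg.time > 2) & (ccg.time <= 15)].mean()
    base = ccg.rate[ccg.time > 30].mean()
    print(f"CCG ({cell.cell_id}): rate on (2,15] ms after a Cspk = {pause:.1f} sp/s "
          f"vs baseline {base:.1f} sp/s (n = {int(ccg.n_trials[0])} triggers)")


if __name__ == "__main__":
    main()
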