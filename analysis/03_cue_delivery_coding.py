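"""Cspk reward coding at cue presentation versus reward delivery.

Per cell: rank-sum comparison of 100-300 ms post-event Cspk counts between
reward conditions, at the cue and at delivery; spike-count fractions in the
cue window; population signed-rank tests across cells.  The expected pattern:
a cue-period effect (higher rate after the large-reward cue) and no delivery
effect.
"""

import numpy as np
import pandas as pd
from _common import RESULTS, get_session
from scipy import stats as sps

from pursuitcspk.data_model import AnalysisParams, select_trials
from pursuitcspk.spiketrains import count_fractions, window_counts
from pursuitcspk.tuning_stats import classify_cue_discrimination, rank_sum_test

P = AnalysisParams()


def main():
    session = get_session()
    trials = select_trials(session)
    rows = []
    fractions = {"large": [], "small": []}
    for cell in session.cells:
        cue = classify_cue_discrimination(cell, trials, P)
        cc = window_counts(cell.cspk, trials, "cue", P.count_window, P)
        dc = window_counts(cell.cspk, trials, "reward", P.count_window, P)
        w_s = (P.count_window[1] - P.count_window[0]) / 1000.0
        row = {"cell_id": cell.cell_id, "cue_p": cue.cue_p, "cue_sign": cue.cue_sign}
        for name, df in (("cue", cc), ("delivery", dc)):
            for cond in ("large", "small"):
                sub = df.loc[df.reward == cond, "count"]
                row[f"{name}_rate_{cond}"] = sub.mean() / w_s
        dl = dc.loc[dc.reward == "large", "count"].to_numpy()
        ds = dc.loc[dc.reward == "small", "count"].to_numpy()
        row["delivery_p"] = rank_sum_test(dl, ds).p_value
        rows.append(row)
        for cond in ("large", "small"):
            fractions[cond].append(count_fractions(cc, cond))
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cue_delivery.csv", index=False)

    n_disc = int((df.cue_p < P.alpha).sum())
    n_pos = int(((df.cue_p < P.alpha) & (df.cue_sign == "large>small")).sum())
    print(f"{n_disc}/{len(df)} cells discriminate reward size at cue "
          f"({n_pos} with large > small)")
    for name in ("cue", "delivery"):
        d = df[f"{name}_rate_large"] - df[f"{name}_rate_small"]
        p = sps.wilcoxon(d).pvalue
        print(f"population {name} effect: mean rate diff {d.mean():+.2f} sp/s, "
              f"signed-rank p = {p:.2g}")
    for cond in ("large", "small"):
        mean_f = pd.DataFrame(fractions[cond]).mean()
        print(f"cue-window Cspk count fractions ({cond}): "
              + ", ".join(f"{k}: {v:.2f}" for k, v in mean_f.items()))


if __name__ == "__main__":
    main()
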