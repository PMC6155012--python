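"""Is the CD45RB+ subpopulation inside the naive bubble phenotypically
distinct?  Bootstrap z-score test of focal medians against resampled
parent medians (B = 10,000).

Reads results/data/cytometry_events.csv, writes results/distinctness.tsv.
"""

from pathlib import Path

from mzatlas import distinctness, synthetic
from mzatlas.panels import PANEL, THRESH
from mzatlas.pipeline import stage_seed

SEED = stage_seed(1, "distinct")
table = synthetic.read_event_csv(Path("results/data/cytometry_events.csv"),
                                 PANEL)

# the "naive bubble": CD27- IgD+ CD10- events, i.e. naive cells plus the
# CD45RB+ precursor subpopulation hiding among them (CD10 excludes
# transitional cells)
naive_bubble = table.select(
    ((table.data["CD27"] < THRESH["pos"])
     & (table.data["IgD"] > THRESH["pos"])
     & (table.data["CD10"] < THRESH["pos"])).to_numpy())
focal = naive_bubble.select(
    (naive_bubble.data["CD45RB"] > THRESH["CD45RB_hi"]).to_numpy())
print(f"naive bubble: {naive_bubble.n_events} events; "
      f"CD45RB+ focal: {focal.n_events} events")

null = distinctness.bootstrap_null(naive_bubble, focal.n_events, B=10_000,
                                   seed=SEED)
res = distinctness.significance_call(
    distinctness.zscore_markers(focal, null), threshold=2.0)

out = Path("results")
out.mkdir(exist_ok=True)
res.table.to_csv(out / "distinctness.tsv", sep="\t", index=False)

flagged = res.table[res.table["flag"]]
print(f"{len(flagged)} of {res.n_markers} markers flagged at |z| >= 2")
for _, r in res.table.sort_values("z", ascending=False).iterrows():
    mark = "*" if r["flag"] else " "
    print(f" {mark} {r['marker']:>7s}  z = {r['z']:+8.1f}  ({r['direction']})")
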