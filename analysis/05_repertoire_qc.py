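"""Read-level and sequence-level QC of the amplicon data.

FASTQ -> quality filter -> MID demultiplex -> primer mask/trim -> duplicate
collapse; then functionality/MID-consistency and sliding-window chimera
filters plus mutation counting on the annotated table.

Reads results/data/, writes results/repertoire/.
"""

from pathlib import Path

import pandas as pd

from mzatlas import repqc, synthetic

DATA = Path("results/data")
OUT = Path("results/repertoire")
OUT.mkdir(parents=True, exist_ok=True)

reads = synthetic.read_fastq(DATA / "reads.fastq")
logs = []
kept, log = repqc.quality_filter(reads)
logs.append(log)
demuxed, log = repqc.demux_mid(kept, synthetic.DEFAULT_MIDS)
logs.append(log)
fwd = {synthetic.DEFAULT_FWD_PRIMER[0]: synthetic.DEFAULT_FWD_PRIMER[1]}
primed, log = repqc.match_primers(demuxed, fwd, synthetic.DEFAULT_REV_PRIMERS)
logs.append(log)
unique = repqc.collapse_duplicates(primed)
for lg in logs:
    print(f"{lg.stage:>18s}: {lg.n_in} in, {lg.retained} kept, "
          f"removed {lg.removed or '{}'}")
print(f"collapsed {len(primed)} reads into {len(unique)} unique sequences "
      f"(duplicate counts sum to {sum(u.duplicate_count for u in unique)})")

rep = synthetic.read_airr(DATA / "repertoire.tsv")
rep_f, log_f = repqc.functionality_filter(rep)
rep_c, log_c = repqc.apply_chimera_filter(rep_f)
for lg in (log_f, log_c):
    print(f"{lg.stage:>22s}: {lg.n_in} in, {lg.retained} kept, "
          f"removed {lg.removed}")

annotated = repqc.annotate_mutations(rep_c)
synthetic.write_airr(annotated, OUT / "repertoire_qc.tsv")

stage_rows = [{"stage": lg.stage, "n_in": lg.n_in, "retained": lg.retained,
               **{f"removed_{k}": v for k, v in lg.removed.items()}}
              for lg in (*logs, log_f, log_c)]
pd.DataFrame(stage_rows).to_csv(OUT / "qc_log.tsv", sep="\t", index=False)

mut = annotated.groupby("subset")["mutation_freq"].median().sort_values()
print("median mutation frequency by subset:")
print(mut.to_string(float_format="%.4f"))
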