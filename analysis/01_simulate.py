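"""Simulate the three data arms with known ground truth.

Writes under results/data/:
  cytometry_events.csv        suspension sample (GALT-like mixture)
  tissue_<t>_rep<r>.csv       six tissue samples (3 tissues x 2 replicates)
  tissue_image.tiff (+ sidecar), truth_<zone>.tiff
  repertoire.tsv              pooled 4-donor AIRR table with truth columns
  reads.fastq                 MID-tagged amplicon reads for donor d1
  sim_config.json             repertoire generator settings + seed
"""

from pathlib import Path

from mzatlas import synthetic
from mzatlas.pipeline import stage_seed
from mzatlas.synthetic import DEFAULT_MIDS as MIDS

SEED = 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

# suspension arm
table = synthetic.gen_cytometry_sample(
    synthetic.default_archetypes(), 5000,
    seed=stage_seed(SEED, "simulate_cyto"))
synthetic.write_event_csv(table, OUT / "cytometry_events.csv")
print(f"cytometry: {table.n_events} events, "
      f"{table.data['truth_subset'].nunique()} subsets")

s = stage_seed(SEED, "simulate_cyto") + 1
for tissue in ["galt", "spleen", "tonsil"]:
    for r in range(2):
        ts = synthetic.gen_tissue_sample(tissue, f"{tissue}{r}", 4000, seed=s)
        s += 1
        synthetic.write_event_csv(ts, OUT / f"tissue_{tissue}_rep{r}.csv")
print("tissue samples: 3 tissues x 2 replicates x 4000 events")

# imaging arm
geom = synthetic.default_tissue_geometry()
img, chans, truth = synthetic.gen_imc_image(
    geom, seed=stage_seed(SEED, "simulate_imc"))
synthetic.write_image(img, chans, OUT / "tissue_image.tiff")
for name, mask in truth.items():
    synthetic.write_mask(mask, OUT / f"truth_{name}.tiff")
print(f"image: {img.shape[0]}x{img.shape[1]} px, {len(chans)} channels, "
      f"zones: {', '.join(truth)}")

# repertoire arm
rep = synthetic.multi_donor_repertoire(seed=stage_seed(SEED, "simulate_rep"))
synthetic.write_airr(rep, OUT / "repertoire.tsv")
cfg = synthetic.RepertoireSimConfig(seed=stage_seed(SEED, "simulate_rep"))
synthetic.write_config(cfg, OUT / "sim_config.json")
d1 = rep[rep.donor == "d1"]
reads = synthetic.gen_reads(d1, MIDS, seed=stage_seed(SEED, "simulate_rep"))
synthetic.write_fastq(reads, OUT / "reads.fastq")
print(f"repertoire: {len(rep)} sequences, "
      f"{rep['clone_id_truth'].nunique()} truth clones, "
      f"{rep['is_chimera_truth'].sum()} chimeras; "
      f"{len(reads)} reads written for donor d1")
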