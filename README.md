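# il17sys

Comparative transcriptomics of psoriasis and cutaneous squamous cell
carcinoma (cSCC), centered on the IL-17 signaling pathway: moderated-t
differential expression, cross-dataset biomarker intersection,
hypergeometric pathway enrichment, and a dynamic activation/inhibition
model of the IL-17 signaling sub-pathway with local sensitivity analysis of
its biological-process outputs.

Psoriasis is a chronic inflammatory skin disease with an elevated risk of
non-melanoma skin cancer; both psoriatic lesions and cSCC show strong
IL-17-driven signatures. This package implements the full analysis chain a
study of that relationship needs, with synthetic cohorts carrying planted
ground truth so every stage is testable without downloading expression
archives.

## What is inside

- **`il17sys.synth`** — synthetic cohorts: Gaussian log2-intensity
  (microarray-like) and negative-binomial count (RNA-seq-like) matrices with
  planted differentially expressed genes (DEGs), plus toy miRNA-target maps.
- **`il17sys.destats`** — per-gene two-group linear fits, empirical-Bayes
  variance moderation (moment matching on log s², moderated t on d₀+d
  degrees of freedom; verified against limma to machine precision), and two
  threshold regimes: stringent (p < 0.005, |log₂FC| > 1, disease vs normal)
  and relaxed (p < 0.05, |log₂FC| > 0.5, subtype contrasts).
- **`il17sys.crossdata`** — DEG-set intersection across datasets,
  miRNA→target joins, and per-gene average expression used to seed the model.
- **`il17sys.enrich`** — upper-tail hypergeometric over-representation
  against the measured universe (p ≤ 0.05 significance), and the
  common-significant-pathway comparison across datasets.
- **`il17sys.pathway`** — the IL-17 sub-pathway as a reaction network:
  activation edges are mass-action conversions (flux k·[S], split equally
  over a source's outbound edges), inhibition edges are catalytic removal
  (flux k·[I]·[T]). Two shipped disease models (psoriasis, cSCC) encode the
  cascade from the IL-17 ligands through the receptor/adaptor complex,
  TRAF6, the TAK1 complex, NF-κB and MAPK/AP-1 arms, into effector families
  (chemokines, antimicrobial peptides, matrix metalloproteinases, cytokines)
  and three terminal biological-process outputs: autoimmune pathology,
  neutrophil recruitment, and immunity to extracellular pathogens.
- **`il17sys.sensitivity`** — fully normalized local sensitivities of the
  process outputs to species initial values (central differences,
  (∂Y/∂X₀)·X₀/Y summarized by its max |·| over time) with the strict > 1.5
  high-sensitivity classification.
- **`analysis/01…06`** — numbered drivers running the whole workflow and
  writing tables under `results/`.

## Worked example

```python
from il17sys.data import load_table5, psoriasis_model_path
from il17sys.pathway import apply_initial_values, load_model, peak, simulate

model = apply_initial_values(load_model(psoriasis_model_path()), load_table5())
trajectory = simulate(model, t_end=10.0)
for process in model.processes:
    t_peak, value = peak(trajectory, process)
    print(f"{process:36s} peak {value:6.2f} at t={t_peak:4.2f}")
```

prints

```
autoimmune_pathology                 peak  28.40 at t=9.50
neutrophil_recruitment               peak  25.58 at t=9.50
immunity_extracellular_pathogens     peak  25.35 at t=9.30
```

i.e. with the published per-disease average expression values as initial
states (unmeasured pathway genes at 0.5, processes at 0), the three
psoriasis process outputs rise immediately and plateau near 28
concentration units around 9.5 time units; the cSCC model reaches about 22
by the end of the 10-unit window. `analysis/06_sensitivity_analysis.py`
then ranks model inputs by summarized normalized sensitivity and applies
the > 1.5 classification.

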