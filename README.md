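# lrprog

Screening ligand-receptor (LR) pairs for association with cancer
patient survival across bulk RNA-seq cohorts, and localizing the
screened pairs to communicating cell-type pairs in single-cell
RNA-seq.

## Who this is for

Tumors are ecosystems: epithelial tumor cells (ETC),
cancer-associated fibroblasts (CAF), tumor-associated macrophages
(TAM) and other cell types signal to each other through
ligand-receptor pairs, and some of those conversations drive outcome.
`lrprog` is for computational biologists who have (i) several bulk
expression cohorts with overall-survival follow-up, (ii) single-cell
data with cell-type annotations from the same tumor type, and (iii) an
LR-pair database, and who want a reproducible answer to: *which LR
pairs are prognostic, which cell types carry them, and which of those
interactions track tumor grade?*

## The method

**Bulk arm — survival screen.** For each LR pair and cohort, patients
are scored by CPM(ligand) + CPM(receptor) and split at the median
(ties go high). High vs low survival is tested with the Peto-Peto
modification of the Gehan-Wilcoxon test — a weighted log-rank
statistic with weights S(t−), the left-continuous pooled Kaplan-Meier
estimate (the ρ = 1 member of the G-ρ family) — and the effect size is
the hazard ratio exp(β̂) from a univariate Cox fit with Efron tie
handling. Per-cohort p-values are combined by Edgington's sum-of-p
method (Irwin-Hall null):

    P(S ≤ s) = (1/k!) Σ_{j=0}^{⌊s⌋} (−1)^j C(k,j) (s−j)^k

and the combined p-values are corrected with Storey q-values
(smoothing-spline π₀ estimate). A pair is **poor-prognostic** if
q < 0.1 and HR > 1 in every cohort, **good-prognostic** if q < 0.1 and
HR < 1 in every cohort.

**Single-cell arm — CCI localization.** Per patient, for every ordered
(sender, receiver) cell-type pair and LR pair, an edge is emitted when
the ligand is detected in ≥ 20% of sender cells and the receptor in
≥ 20% of receiver cells, weighted by the product of cell-type mean
expressions. The screened pairs' **adjusted enrichment** per cell-type
pair is (m_p/n_p)·(N/M) averaged over patients (m_p screened and n_p
total pairs detected there; M screened-set size, N database size —
value 1 means "detected at background rate"). A grade screen pools all
edge weights in grade-4 patients and keeps screened-pair edges above
the third quartile.

A fully seeded synthetic-data generator plants known prognostic pairs
and known communication edges, so every stage is testable end to end
(see `docs/methods.md` for the model and its limits).

## Worked example

```python
from lrprog import (SyntheticConfig, PlantedEdge, gen_bulk_cohorts,
                    gen_single_cell, screen_pairs, adjusted_enrichment,
                    enrichment_difference)
from lrprog.edges import extract_edges_all
from lrprog.simulate import gene_universe
from lrprog.survival import screen_table

# a small synthetic study: 2 cohorts, 100 LR pairs, 5 poor + 5 good
# planted prognostic pairs, the 5 poor pairs signaling ETC -> TAM
config = SyntheticConfig(
    n_cohorts=2, n_patients_per_cohort=120, n_genes=2000, n_lr_pairs=100,
    n_poor_planted=5, n_good_planted=5, effect_log_hr=1.0,
    n_sc_patients=6, cells_per_patient=300,
    grade_assignment=(2, 2, 3, 3, 4, 4),
    planted_edges=tuple(PlantedEdge("ETC", "TAM", i, 8.0) for i in range(5)),
    seed=7,
)
cohorts, truth = gen_bulk_cohorts(config)
_, pairs = gene_universe(config)

results = screen_pairs(cohorts, pairs, q_threshold=0.1)
table = screen_table(results).sort_values("q_value")
print(table[["ligand", "receptor", "combined_p", "q_value", "mean_hr",
             "prognostic_class"]].head(6).to_string(index=False))
```

prints

```
ligand receptor   combined_p  q_value  mean_hr prognostic_class
 L0006    R0006 2.547085e-07 0.000025 0.452173             good
 L0009    R0009 2.371007e-05 0.001186 0.543907             good
 L0005    R0005 6.027091e-05 0.002009 0.557952             good
 L0008    R0008 1.572224e-04 0.003931 0.619826             good
 L0003    R0003 1.215577e-03 0.024312 2.190577             poor
 L0001    R0001 4.025318e-03 0.067089 1.446741             poor
```

The top hits are planted pairs: pairs 0–4 were planted as
poor-prognostic (true HR e^1.0 ≈ 2.7 per median split) and pairs 5–9
as good-prognostic; the recovered mean HRs sit on the expected side of
1 and the q-values separate them sharply from the 90 null pairs.
Continuing with the single-cell arm:

```python
poor = [r.pair for r in results if r.prognostic_class == "poor"]
good = [r.pair for r in results if r.prognostic_class == "good"]
sc_data = gen_single_cell(config, truth)
edge_sets = extract_edges_all(sc_data, pairs)
diff = enrichment_difference(
    adjusted_enrichment(edge_sets, poor, pairs),
    adjusted_enrichment(edge_sets, good, pairs),
).sort_values("difference", ascending=False)
print(diff.head(3).to_string(index=False))
```

prints

```
sender receiver     poor     good  difference
   ETC      EMT 1.452225 0.783190    0.669035
   ETC      ETC 1.454703 0.786875    0.667828
   CAF      ETC 1.447665 0.781703    0.665962
```

Poor-prognostic pairs are enriched (values > 1) wherever the planted
sender/receiver cell types participate, and depleted for good pairs.
At this miniature scale the top cell-type pairs are near-ties among
ETC-involving interactions with ETC→TAM close behind; at the package's
default study scale (10 patients, 10 planted pairs) ETC→TAM ranks
first, which is what the acceptance suite asserts.

The same analysis runs from the shell:

```bash
lrprog simulate --config sim.yaml --out-dir sim/
lrprog screen --cohort c0=sim/cohort0_expression.tsv,sim/cohort0_clinical.csv \
              --cohort c1=sim/cohort1_expression.tsv,sim/cohort1_clinical.csv \
              --lr-db sim/lr_pairs.tsv --already-cpm --out results.tsv
lrprog edges --sc sim/SC00/matrix.mtx,sim/SC00/metadata.csv \
             --lr-db sim/lr_pairs.tsv --out edges.tsv
lrprog enrich --edges edges.tsv --screen results.tsv \
              --lr-db sim/lr_pairs.tsv --out enrichment.tsv
lrprog grade-screen --edges edges.tsv --meta sim/SC00/metadata.csv \
                    --screen results.tsv --grade 4 --out grade4.tsv
```

or as one orchestrated run (`lrprog run --config pipeline.yaml`) that
writes `results.tsv`, `edges.tsv`, `enrichment.tsv`, `support.tsv`,
`grade_screen.tsv` and a JSON manifest with checksums; reruns with the
same config are byte-identical.

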