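# desertniche

Quantitative analysis of capture-mark-recapture (CMR) trapping studies of
desert rodent communities: population abundance by minimum number known
alive, spatial niche breadth and overlap, habitat
productivity/concealment indices, environmental-factor screening, and
Hellinger-transformed redundancy analysis (RDA) with permutation-gated
forward selection. It is aimed at community ecologists analysing
grid-trapping studies (one trapping grid per plot, multi-day sessions,
repeated seasons and years) who want the whole chain — from raw capture
records to a constrained-ordination table — as tested, scriptable Python.

Because field CMR datasets are rarely deposited, the package ships a
synthetic-study generator with known latent truth (per-plot abundances,
occupancy evenness, factor linkages), so every stage of the pipeline can be
exercised and validated without any external data.

## The statistics implemented

**Abundance.** For each species, plot and trapping session *t*,

    MNKA(t) = a + b

where *a* is the number of distinct individuals caught during session *t*
and *b* the number of marked individuals caught both before and after *t*
but not during it. MNKA is a lower bound on abundance with a negative bias
that is largest at the first and last sessions (no bracketing information
exists there).

**Spatial niche breadth** of species *i* over *r* plots (Shannon–Wiener,
normalised):

    B_i = [lg Σ_j N_ij − (1/Σ_j N_ij) Σ_j N_ij·lg N_ij] / lg r        ∈ [0, 1]

with N_ij the per-plot MNKA. Algebraically B_i = H/ln r for the Shannon
entropy H of the use proportions: 1 for uniform use, 0 for single-plot use.

**Spatial niche overlap** between species *i* and *k*
(Colwell–Futuyma/Schoener):

    O_ik = 1 − ½ Σ_j |N_ij/N_i − N_kj/N_k|                             ∈ [0, 1]

**Habitat indices** per plot: shrub average height AH = (LH+MH+SH)/3,
density Den = IN/100 m², coverage C = (3.14·SR²·Den)/100 m² (SR in metres),
total coverage TC.S = ΣC_i, biomass TB = (P·DW·Den)/100; plus Shannon,
Gini–Simpson and Pielou diversity of the rodent, shrub and grass
communities. Together with soil moisture/hardness by depth layer and
monthly meteorology these form a 31-column plot × factor table.

**Factor screening.** A seeded random-forest regression of each species'
plot-level use on the factor table augmented with row-permuted *shadow*
copies of every factor; factors whose permutation importance exceeds the
mean (resp. maximum) shadow importance have high (resp. very high)
contribution. Pooled selections are then cleaned of multicollinearity by
iterative variance-inflation-factor filtering (drop the worst column while
any VIF ≥ 10).

**Ordination.** The species block is Hellinger-transformed, factors are
z-scored, and RDA (PCA of the fitted values of the multivariate regression
of Y on X) partitions variance into canonical and residual eigenvalues.
Significance uses the permutation pseudo-F with the add-one rule
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); model parsimony uses Ezekiel's
adjusted R² = 1 − (1 − R²)(n−1)/(n−m−1). Forward selection admits the
best adjusted-R²-gain candidate whose conditional permutation test passes
α, gated by a global significance pre-test and an adjusted-R² ceiling.

## Worked example

```python
import desertniche as dn

cfg = dn.SimulationConfig()                      # the default study design
print("cage-days:", cfg.trap_days())
captures, truth = dn.simulate_study(cfg, seed=42)
print("capture records:", len(captures))

histories = dn.build_histories(captures, validate=False)
mnka_df = dn.mnka_table(histories)
print("ZW on plot P01, MNKA by session:",
      dn.mnka_series(histories[("ZW", "P01")]).tolist())

breadths = dn.breadth_table(mnka_df)
summary = dn.niche.summarize_index_table(breadths, "breadth",
                                         ["species", "season"])
print(summary.round(3).to_string(index=False))
```

prints

```
cage-days: 80640
capture records: 9878
ZW on plot P01, MNKA by session: [6, 11, 4, 13, 11, 8, 9, 3, 5, 7, 2, 3, 9, 10, 7]
species season  mean    se  n_years
     MZ autumn 0.789 0.013        5
     MZ spring 0.745 0.019        5
     MZ summer 0.774 0.017        5
     SZ autumn 0.921 0.016        5
     SZ spring 0.916 0.010        5
     SZ summer 0.922 0.010        5
     WZ autumn 0.849 0.012        5
     WZ spring 0.820 0.018        5
     WZ summer 0.846 0.013        5
     ZW autumn 0.961 0.003        5
     ZW spring 0.952 0.008        5
     ZW summer 0.952 0.005        5
```

The design comprises 56 traps × 24 plots × 4 days × 3 seasons × 5 years
= 80,640 cage-days. The 15-session MNKA series for one gerbil (ZW)
population on plot P01 tracks its simulated abundance; the summary table is
the mean ± standard error of each species' spatial niche breadth across the
five study years, per season — the generator's evenness dials make MZ the
spatial specialist and ZW the generalist.

The full pipeline (MNKA → niche metrics → factor table → screening → VIF →
RDA with forward selection) runs end to end from a shell:

```bash
desertniche run-all --simulate --seed 7 --outdir out/
```

writing `mnka.csv`, `niche_breadth*.csv`, `niche_overlap*.csv`,
`factor_table.csv`, `screening_report.json`, `vif_report.json`,
`rda_result.json`, `table4.csv` and a hash manifest. Subcommands
`simulate`, `mnka`, `niche`, `habitat` and `screen` run individual stages
on CSV inputs with the schemas documented in their `--help`.

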