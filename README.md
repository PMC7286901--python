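# bufferscan

Quantitative toolkit for studying **metabolic mutational buffering** — the
ability of a cell's metabolic state (its pool of osmolytes and other small
molecules) to mask the phenotypic cost of destabilizing protein mutations.
The package implements, on top of a synthetic-data layer with known ground
truth, the analysis machinery such studies rely on:

1. **Arrest-chase kinetic model.** A template pool S (mRNA/ribosome
   complexes) produces nascent polypeptide U at rate *k*<sub>trans</sub>;
   U either folds to the native state F with rate constant *k*<sub>f</sub>
   or is degraded with *k*<sub>deg</sub>; an inhibitor I (chloramphenicol-like)
   quenches S with second-order constant *k*<sub>block</sub> when dosed at
   *t*<sub>arrest</sub>:

   dS/dt = −*k*<sub>block</sub>·S·I  dU/dt = *k*<sub>trans</sub>·S − (*k*<sub>f</sub> + *k*<sub>deg</sub>)·U  dF/dt = *k*<sub>f</sub>·U

   The chase observable is intact protein U + F after arrest. A closed-form
   solution of the linear (pseudo-first-order) system serves as an analytic
   oracle for the numerical integrator, and a folding-rate scan shows how
   faster folding masquerades as slower degradation at constant
   degradative capacity.

2. **Deep-mutational-scanning (DMS) scoring.** Mutant read counts are
   coverage-normalized, averaged over replicates, converted to enrichment
   scores *E* = (selected frequency)/(unselected frequency) and z-scored
   (*z* = (*E* − mean *E*)/sd *E*), with activity classes and cross-strain
   buffering calls from a 99% OLS prediction band on log-normalized counts.

3. **MIC pipeline.** OD600 growth across an antibiotic dilution series is
   normalized to the unselected well; the MIC is the lowest tested
   concentration with mean growth below a threshold (default 0.1), and
   mutant MICs are reported as percent of the wild-type MIC in the same
   strain.

4. **Kinetic fitters.** Single-exponential refolding rates
   (y₀ + A(1 − e^(−kt))), chloramphenicol-chase decays
   (P + (1 − P)e^(−k·t)), two-state thermal-melt midpoints (Tm) with linear
   baselines, and GFP/mCherry reporter-ratio summaries
   (log₂ of the median-ratio fold-change).

All inputs are plain TSV/CSV; all generators are seeded and emit JSON truth
sidecars, so every stage is testable without any external data.

## Worked example

```python
import numpy as np
import bufferscan as bs

# folding-rate scan of the arrest-chase model (k_deg fixed at 0.01 1/s)
params = bs.SimParams()          # S0=1000 µM, I dosed to 1000 µM at t=300 s
t = np.linspace(0, 1200, 601)
scan = bs.scan_folding_rates(params, [1e-3, 1e-2, 1e-1], t)
for kf, val in zip(scan.kf_values, scan.intact_at(1200.0)):
    print(f"{kf:<10g} {val:.2f}")

traj = bs.simulate_chase(params.with_(k_f=0.0), t)
fit = bs.apparent_degradation_rate(traj, params.t_arrest)
print(f"apparent degradation rate at k_f=0: {fit.k_app:.5f} 1/s")

# a synthetic DMS selection with one mutant planted 10-fold down in strain B
cfg = bs.GeneratorConfig(seed=17, depth=200_000,
                         planted_log_fold={"m0042": -np.log(10)})
data = bs.gen_count_table(cfg)
result = bs.score_table(data.table, ci_level=0.99)
comp = result["comparisons"]["CSH4_vs_WG350"]
print("reduced mutants:", list(comp.flags.index[comp.flags == "reduced"]))
```

prints

```
0.001      272.77
0.01       1500.00
0.1        2727.27
apparent degradation rate at k_f=0: 0.01000 1/s
reduced mutants: ['m0042']
```

Intact protein surviving the chase grows monotonically with the folding
rate — a tenfold faster folder keeps roughly tenfold more protein out of
the degradation pathway — and with no folding at all the fitted apparent
rate equals the degradation constant exactly. In the DMS half, the one
mutant whose frequency was planted tenfold lower in the second strain is
the only one falling below the 99% band: the pipeline's cross-strain
"reduced buffering" call recovers the planted truth.

The same stages are available from the command line:

```sh
bufferscan simulate --t-end 1200 --n-points 600 --scan-kf 1e-3,1e-2,1e-1 --out scan.csv
bufferscan generate counts --seed 17 --out data/
bufferscan score --counts data/counts.tsv --coverage data/coverage.tsv \
    --samples data/samples.tsv --ci 0.99 --out scores.tsv
bufferscan mic --growth growth.tsv --threshold 0.1 --out mic.tsv
bufferscan fit --trace trace.csv --kind refolding --out fit.tsv
bufferscan demo --out demo/ --seed 17
```

`bufferscan demo` runs everything end-to-end on synthetic data and writes
tables, advisory plots and a manifest with checksums; two runs with the
same seed produce byte-identical tables.

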