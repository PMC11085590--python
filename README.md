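# rootkin

Quantitative genetics of the root growth engine: a tested pipeline linking
root elongation-zone kinematics to genotype in recombinant inbred line
(RIL) populations, and relating the kinematic traits to gravitropic
bending.

## The problem

The Arabidopsis primary root elongates because cells in a ~0.5 mm
elongation zone behind the tip expand. Time-lapse imaging yields, for each
root, a *velocity point cloud*: displacement velocity `v` of root material
versus distance from the tip `x`, in the tip's reference frame. `rootkin`
starts from those point clouds and carries the analysis through to genome
scans and multivariate trait-to-bending correlations. It is aimed at plant
quantitative geneticists who phenotype growth-zone kinematics at
population scale.

## The model and statistics

**Velocity profile.** Each cloud is fit by nonlinear least squares to the
flexible logistic function

    v(x) = vf · [1 + e^(−k(x−x0))]^(−1/n)

with plateau velocity `vf` (mm/h), location `x0` (mm), steepness `k`
(1/mm), and asymmetry `n`. Replicate fits (7–10 roots per RIL) are
averaged parameter-wise to give each line's profile. The spatial
derivative of `v` is the relative elemental growth rate
REGR(x) = vf·(k/n)·u·(1+u)^(−(1+1/n)) with u = e^(−k(x−x0)) — the local
strain rate of the tissue, reported in % h⁻¹. Four traits summarise each
line's elongation zone:

| trait | closed form |
|---|---|
| elongation rate | `vf` |
| maximum REGR | `100·vf·k·(1+n)^(−(1+1/n))` |
| position of maximum REGR | `x0 − ln(n)/k` |
| zone length | width of `{x : REGR ≥ 0.2·REGR_max}` |

**QTL mapping.** Genotype probabilities at a 1-cM pseudomarker grid come
from a two-state hidden Markov model for selfed RILs (transition fraction
`R = 2r/(1+2r)`, Haldane `r`, genotyping error rate 0.001). Each trait is
scanned by single-QTL Haley–Knott regression on P(BB):
`LOD = (N/2)·log10(RSS0/RSS1)`. Genome-wide 5% thresholds come from
phenotype permutations; peaks are reported with 1.5-LOD support intervals,
additive effects, and the variance explained by a joint fit of all
significant loci.

**Gravitropism.** Tip-angle time courses (241 samples, every 2 min for
8 h after a 90° rotation) are summarised by PCA (PC1 score), by the
maximum swing rate (peak sliding-window slope, °/h), and by canonical
correlation analysis between the z-scored kinematic-trait block and the
first five PC scores, with an empirical permutation threshold for the
first canonical correlation.

A seeded synthetic-data module generates every input — RIL genotypes on a
5-chromosome map, planted-QTL profile parameters, replicate point clouds,
and paired gravitropism experiments — so the whole pipeline is testable
end to end.

## Worked example

```python
from rootkin.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=11, out_dir="demo", n_perm=1000)
res = run_pipeline(cfg)   # 160 RILs, 3 planted QTL, 2 gravitropism experiments
for h in res.hits:
    print(f"{h.trait:20s} {h.chromosome}@{h.position:5.1f}  LOD {h.lod:5.2f}  "
          f"CI [{h.ci_lo:5.1f}, {h.ci_hi:5.1f}]")
```

prints

```
elongation_rate      chr1@ 20.9  LOD 24.45  CI [ 20.1,  21.6]
regr_max             chr1@ 20.9  LOD 10.68  CI [ 20.1,  21.6]
regr_max             chr3@ 39.4  LOD  6.02  CI [ 36.8,  41.1]
regr_max_position    chr5@ 77.2  LOD 11.30  CI [ 74.8,  78.7]
zone_length          chr3@ 38.5  LOD 16.56  CI [ 37.7,  38.5]
```

The demo plants additive QTL on `vf` at chr1@21.5, on `k` at chr3@39.7,
and on `x0` at chr5@76.7; every planted locus is recovered inside its
1.5-LOD interval, and the `k` locus shows up for two traits (maximum REGR
and zone length) because both derive from the steepness parameter —
pleiotropy of exactly the kind a multi-trait scan should expose. The run
directory also contains the permutation thresholds (~2.7 LOD here), the
per-trait variance explained by the significant loci, PC scores with PC1
carrying ~93% of curve variance, and the CCA report (first canonical
correlation 0.293 against a 0.348 permutation threshold in this
realisation).

The same stages are available as a CLI for file-based workflows:

```sh
rootkin simulate --seed 1 --out sim/
rootkin scan --genotypes sim/genotypes.csv --map sim/map.csv \
             --phenotypes traits.csv --out lod.csv
rootkin run-all --seed 1 --out run/
```

## Layout

- `rootkin.kinematics` — velocity model, REGR, fitting, trait extraction
- `rootkin.qtlscan` — pseudomarkers, HMM genotype probabilities, HK scan,
  permutations, peaks
- `rootkin.gravimetrics` — curve PCA, swing rate, Pearson matrix, CCA
- `rootkin.synthdata` — seeded generators for all inputs
- `rootkin.io` / `rootkin.pipeline` / `rootkin.cli` — table formats,
  orchestration, command line

See `docs/methods.md` for modelling assumptions, defaults, and known
limitations.
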