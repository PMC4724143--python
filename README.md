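# obsim — obstetrics-service intensification and drive-time access

`obsim` simulates what happens to geographic access when obstetrics services
are *intensified* — concentrated into fewer, larger hospitals by closing
low-volume facilities. It is aimed at health-services researchers and
health-policy analysts who want to quantify the trade-off between hospital
volume (a proxy for quality and staffing efficiency) and the share of women
of childbearing age who can still reach a delivery ward quickly.

The pipeline:

1. **Synthetic geography** — a rectangular region tiled by 1-km² grid cells
   holding the female population aged 15–49, clustered in urban centres;
   contiguous municipalities grouped into medical service areas (MSAs);
   hospitals with right-skewed monthly delivery volumes and correlated
   obstetrician/midwife staffing (gamma marginals coupled through a shared
   latent facility-size factor); an undirected road network with road-class
   speeds in 10–80 km/h.
2. **Drive-time access** — exact shortest-path minutes from every cell to
   every hospital (edge weight = length/speed × 60), classified into
   ≤ 30 min, 30–60 min and > 60 min bands.
3. **Closure scenarios** at a target hospital count k:
   * **S1 (volume)** — keep the k highest-volume hospitals;
   * **S2 (MSA + volume)** — guarantee each MSA its top hospital first,
     then fill by volume;
   * **S3 (max-cover)** — the maximal covering location problem:
     maximize Σ_c pop_c·y_c subject to y_c ≤ Σ_{h∋c} x_h, Σ_h x_h = k,
     x, y binary, where h∋c means cell c is within 30 min of hospital h
     (greedy with the 1 − 1/e guarantee, or exact via enumeration/MILP);
   * a **fixed designation set** (academic hospitals + perinatal medical
     centres) independent of k.
4. **Metrics** — population coverage P(≤30 min) nationally and per
   municipality; the Gini coefficient
   G = Σᵢⱼ|xᵢ − xⱼ| / (2n²x̄) of per-municipality coverage fractions;
   reallocation accounting (deliveries and staff in closed hospitals that
   retained ones must absorb); and target adjustment k = round(N·r) for a
   survey reporting fraction r (default 0.985, mapping national estimates
   1000/800/600 to 985/788/591).

## Worked example

```python
import obsim

syn = obsim.SyntheticConfig(seed=7, region_width_km=80, region_height_km=60,
                            n_msas=8, municipalities_per_msa=4,
                            n_urban_clusters=5, total_female_pop=600_000,
                            n_hospitals=60,
                            road_class_speeds_kmh=(10.0, 30.0, 50.0, 80.0))
cfg = obsim.RunConfig(synthetic=syn, national_targets=(50, 40, 30),
                      scenarios=("S1_volume", "S2_msa_volume",
                                 "S3_maxcover_greedy"),
                      out_dir="results/example", log_level="WARNING")
report = obsim.run(cfg)
b = report.baseline
print(f"baseline: {len(b.retained)} hospitals, "
      f"coverage {100*b.coverage.fraction:.1f} %, Gini {b.gini_value:.3f}")
for r in report.rows:
    print(f"{r.scenario:<20} k={r.target_k:<3} "
          f"coverage {100*r.coverage.fraction:5.1f} %  "
          f"Gini {r.gini_value:.3f}  births absorbed "
          f"{r.absorption.births_absorbed:7.1f}")
```

prints

```
baseline: 60 hospitals, coverage 99.5 %, Gini 0.085
S1_volume            k=49  coverage  99.5 %  Gini 0.088  births absorbed    64.3
S1_volume            k=39  coverage  99.2 %  Gini 0.097  births absorbed   210.5
S1_volume            k=30  coverage  98.7 %  Gini 0.171  births absorbed   441.8
S2_msa_volume        k=49  coverage  99.5 %  Gini 0.088  births absorbed    64.3
S2_msa_volume        k=39  coverage  99.2 %  Gini 0.097  births absorbed   210.5
S2_msa_volume        k=30  coverage  98.9 %  Gini 0.131  births absorbed   446.0
S3_maxcover_greedy   k=49  coverage  99.5 %  Gini 0.085  births absorbed   561.5
S3_maxcover_greedy   k=39  coverage  99.5 %  Gini 0.085  births absorbed   859.3
S3_maxcover_greedy   k=30  coverage  99.5 %  Gini 0.085  births absorbed  1199.7
```

The national targets 50/40/30 are first scaled by the reporting fraction
(→ k = 49/39/30). Reading the table: closing half the hospitals by volume
alone (S1, k=30) costs 0.8 points of coverage and nearly doubles
inter-municipality inequity (Gini 0.085 → 0.171); adding the MSA guarantee
(S2) softens the inequity rise; choosing survivors to maximize coverage
(S3) holds coverage at the baseline level — but it closes the *largest*
hospitals' volume instead, so retained facilities must absorb far more
deliveries (1199.7 vs 441.8 births/month at k=30). `out_dir` also receives
`coverage_curve.csv`, `gini_curve.csv`, `absorption.csv`,
`municipality_coverage.csv`, `retained.csv` and a provenance-stamped
`report.json`.

The same pipeline is scriptable from a shell:

```sh
obsim generate --config synth.yaml --out geo/
obsim run --geo geo/ --config run.yaml --out results/
obsim report --results results/ --format csv
```

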