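# neonet

Origin–destination networks of neonatal hospitalization displacement.

## The problem

When a newborn needs hospital care during the neonatal period (days 0–27 of
life) and the service does not exist in the mother's municipality of
residence, the admission happens somewhere else.  Each distinct pair between
the municipality of residence (origin) and the municipality where the
admission occurred (destination) is a *displacement*.  Mapped over a whole
state and a decade, these displacements describe how regionalized networks
of obstetric and neonatal care actually route patients — which municipalities
act as service poles, how far families travel, and whether displacement stays
inside the health region that is supposed to organise it.

`neonet` implements that analysis as a tested, reusable pipeline for
analysts working with SIH-SUS-style admission records, SINASC-style birth
records, SIM-style death records and CNES-style bed registries, and ships a
synthetic-data generator that emulates those systems for a state of 22
health regions in 4 macroregions, so the entire pipeline runs end-to-end
with no access to the real databases.

## The statistics at its core

For an origin municipality $O_i$ with $K$ destinations $D_k$ receiving
$f_k$ admissions each, the **mean outgoing edge** is the flow-weighted mean
seat-to-seat great-circle distance

$$d_i = \frac{\sum_{k=1}^{K} f_k \, d(O_i, D_k)}{\sum_{k=1}^{K} f_k},$$

and for health region $j$ with $n_j$ origin municipalities the regional
displacement distance is the outflow-weighted mean

$$m_j = \frac{\sum_{i=1}^{n_j} F_i \, d_i}{\sum_{i=1}^{n_j} F_i},
\qquad F_i = \sum_k f_k .$$

Alongside $m_j$, the pipeline computes per region × biennium (2008-2009 …
2018-2019): the share of neonatal admissions displaced outside the residence
municipality, the share of displacements staying within the health region,
NICU beds per 1,000 live births, the shares of live births with weight
< 1,500 g, gestational age < 28 weeks, 5-minute Apgar ≤ 7, maternal age
≥ 35 years, and the neonatal mortality rate (TMN, deaths at 0–27 days per
1,000 live births).  Changes between two biennia $A$ and $B$ are reported as
percent variation $[(B-A)/A] \cdot 100$.

Displacements are rendered as directed graphs (nodes at municipality seat
coordinates, coloured by macroregion; edge weight = outflow; node metrics =
in-degree and inflow) exportable to GEXF/GraphML for Gephi.  Biennial trends
and TMN associations are fitted with random-intercept linear models
($y_{jt} = \beta_0 + \beta_1 t + u_j + \varepsilon_{jt}$, REML), with
regions as the observational unit, plus a simulation harness that checks
slope bias and CI coverage at the 22 × 6 panel shape.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic conditions and write their tables under `results/`:

```
python analysis/01_simulate.py --seed 1
python analysis/02_displacement.py
python analysis/03_region_metrics.py
python analysis/04_networks.py
python analysis/05_trend_models.py
python analysis/06_recovery_study.py
```

With seed 1, `02_displacement.py` prints

```
admissions: 188,898; neonatal (0-27 d): 150,986
displaced in-state: 56,777; same municipality: 93,663; out of state: 546 (0.95% of displaced admissions)
  2008-2009:   7,369 displaced admissions over 2,227 distinct OD pairs
  ...
  2018-2019:  11,889 displaced admissions over 3,059 distinct OD pairs
```

— the age filter kept 151k of 189k admissions, ~38% of them displaced, with
the configured ~1% out-of-state share, and demand growing across biennia.
`03_region_metrics.py` then reports

```
2008-2009: flow-weighted distance 52.47 km; displaced 38.2% of admissions; 76.3% of displacements intra-regional; TMN 9.01/1,000
2018-2019: flow-weighted distance 54.07 km; displaced 37.6% of admissions; 75.3% of displacements intra-regional; TMN 7.55/1,000
```

and `05_trend_models.py` fits the biennial trends, e.g. a declining TMN
(slope −0.276 per biennium, 95% CI −0.353; −0.200) and rising NICU bed
supply, with the three TMN models agreeing on the biennium effect.
`06_recovery_study.py` confirms the estimator: over 500 simulated panels the
mean slope estimate is −0.347 for a true −0.35 (bias within Monte-Carlo
error) with 96.4% CI coverage.

The same steps are available as a CLI (`neonet synth`, `neonet displace`,
`neonet metrics`, `neonet network`, `neonet trends`, `neonet tmn-model`);
see `neonet --help`.

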