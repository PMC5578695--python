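# meiomap

Meiotic recombination mapping from yeast tetrad genotypes.

In a hybrid *Saccharomyces cerevisiae* diploid, tens of thousands of SNPs
distinguish the two parental genomes. Sequencing the four spores of a
tetrad gives, for each chromosome, a 4 × M matrix of parental-origin
calls. Normal Mendelian segregation is 2:2 at every marker; meiotic
recombination leaves two kinds of fingerprints:

* a **crossover (CO)** changes *which* two spores carry one parent's
  allele between consecutive 2:2 markers (a phase change);
* a **gene conversion tract** produces a run of 3:1 / 1:3 (or 4:0)
  markers where information was copied from one homolog onto the other.

`meiomap` turns those matrices into called events, merges events lying
within 5 kb of each other, and classifies each group into the standard
taxonomy: **E1** simple noncrossover (NCO), **E2** simple CO (with or
without a continuous conversion tract), **E3** CO with discontinuous
conversion, **E4** discontinuous NCO, **E5/E5A** double COs, **E6**
multi-chromatid conversions, **E7** complex events. Per-tetrad totals
(CO = E2+E3, NCO = E1, IH = all interhomolog events, a rough proxy for
double-strand-break number) feed genome-wide statistics: Welch t-tests
on count means, rank-sum/KS tests on tract-length distributions, and
per-chromosome OLS regressions of mean counts on chromosome size.

The package also covers the classical assays used alongside genome-wide
maps — fluorescent-spore tetratype frequency with χ² phenotype calls,
Perkins map distances (cM = 100·(TT/2 + 3·NPD)/n ± SE), spore-viability
distributions with the meiosis-I nondisjunction signature, and
Luria–Delbrück fluctuation analysis of reversion rates by the
Lea–Coulson method of the median (r̃ = m·(1.24 + ln m), rate = m/N,
order-statistic 95% CIs, fold change vs wild type) — plus a forward
meiosis simulator with per-event ground truth: ~90 COs per meiosis
placed by a stationary gamma-renewal process (shape > 1 models
crossover interference), lognormal conversion tracts with medians near
1.4–1.8 kb, discontinuous tracts from patchy heteroduplex repair,
genotyping error, and the tetrad-shared 4:0 marker artifacts that the
analysis masks before calling.

## Worked example

```python
from pathlib import Path
from meiomap import GenomeMap, RunConfig, SimParams, run_pipeline

config = RunConfig(n_tetrads=5, seed=42, outdir=Path("scratch/example_run"),
                   genome=GenomeMap(), sim=SimParams(marker_spacing_mean=1000))
tables = run_pipeline(config)
print(tables["summary"].to_string(index=False))
```

prints (see `examples/01_simulate_and_map.py`):

```
tetrad_id  E1  E2  E3  E4  E5  E5A  E6  E7  CO  NCO  NCO_disc  IH_total
       t1  21  75   0   0   1    0   2   2  75   21         0       101
       t2  18  85   1   0   0    0   1   1  86   18         0       106
       t3  20  70   1   0   1    1   0   0  71   20         0        93
       t4  29  78   3   1   1    0   0   2  81   29         1       114
       t5  35  87   4   0   2    0   0   3  91   35         0       131
```

Each row is one meiosis: `t2` had 86 crossovers (85 simple E2, one E3
with discontinuous conversion) and 18 simple noncrossover conversions;
106 interhomolog events in total. The bundled `recall` table compares
these calls with the simulator's ground truth — called CO counts track
the true counts to within about one event, and every
chromatid-identifiable conversion tract is assigned to the correct
strand.

The other scripts in `examples/` each demonstrate one capability:
hand-built segregation matrices (`02`), genotype-vs-genotype statistics
(`03`), tetratype/map-distance assays (`04`) and fluctuation analysis
(`05`). A thin CLI mirrors the stages:

```bash
meiomap simulate -n 10 --seed 7 -o run/
meiomap call run/segregation.tsv -o run/
meiomap mapdist --pd 48 --tt 50 --npd 2     # -> 31.00 ± 4.59 cM
meiomap fluctuation -N 1e8 1 2 1 0 2 1 3 1 2 1
```

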