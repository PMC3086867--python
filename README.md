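# kinforage

Evolution of altruism in group-structured populations of foraging robots —
a desk-scale simulator for quantitative tests of **Hamilton's rule**,
*rb* − *c* > 0.

## The problem

Hamilton's rule predicts when a costly helping behaviour spreads: whenever
the relatedness *r* between actor and beneficiary exceeds the cost/benefit
ratio *c/b*.  Testing the rule quantitatively requires measuring *r*, *c*
and *b* exactly — essentially impossible in natural systems.  This package
re-creates an experimental-evolution design where all three are set by
construction: groups of 8 neural-network-controlled robots push food items
to a white wall in a 50×50 cm arena; a delivered item is either **kept**
(reward *c* to the collector) or **shared** (*b*/7 to each of the seven
group-mates), as decided by the collector's third network output.
Within-group relatedness is fixed by building groups from clones of
randomly drawn founders: the schemes {8}, {7,1}, {6,1,1}, {3,3,2} and
{1×8} give *r* = 1, 0.7492, 0.5346, 0.2492 and 0 under the regression
definition

    r = (p_group − p_pop) / (1 − p_pop),

the within-group vs population probabilities of sampling a clone as
social partner (self-pairs excluded).  Selection is population-wide
roulette on inclusive fitness

    fᵢ = c·n_selfish,ᵢ + (b/7)·Σ_{j≠i} n_shared,j

followed by single-point crossover (p = 0.005), per-bit mutation
(p = 0.005) and re-cloning into groups.  The package also implements the
mutation-effect screens used to show that the genotype–phenotype map
violates the textbook assumptions behind the rule: pleiotropy (one ±32
point mutation affecting both foraging performance and altruism),
epistasis (a contrast-of-differences z over F(0), F(A), F(B), F(AB)) and
departures from weak selection (>25% trait changes from one mutation).

It is intended for researchers in social evolution and evolutionary
robotics who want a fast, fully reproducible sandbox in which *r* and
*c/b* are exact dials.  See `docs/methods.md` for the model in detail.

## Worked example

```python
import kinforage as kf

# exact relatedness of the 1:7 clone scheme in 200 groups of 8
comp = kf.GroupComposition((7, 1), m=200)
print(round(kf.regression_relatedness(comp).r_analytic, 4))   # 0.7492

# evolve one scaled-down population: clonal groups, cheap sharing
log = kf.run_evolution(kf.GroupComposition.from_name("r100", m=20),
                       ratio=0.01, generations=40, seed=7, trials=3)
t = log.table
print(f"altruism {t.mean_altruism.iloc[0]:.2f} -> {t.mean_altruism.iloc[-1]:.2f}")
print(f"items/trial {t.mean_items_per_trial.iloc[0]:.2f} -> "
      f"{t.mean_items_per_trial.iloc[-1]:.2f}")
```

prints

```
0.7492
altruism 0.50 -> 0.96
items/trial 0.10 -> 0.42
```

— with *r* = 1 > *c/b* = 0.01, the share fraction of delivered items
climbs from its neutral starting level toward fixation while foraging
efficiency improves; the same run with unrelated groups (`"r0"`) drives
altruism toward zero instead.

The same experiments are available from the shell:

```sh
kinforage relatedness --scheme r75            # r=0.7492
kinforage evolve --scheme r100 --ratio 0.01 --m 20 --generations 40 \
                 --replicates 2 --trials 3 --seed 7 --out runs/demo
kinforage screen pleiotropy --population runs/demo/population_rep000.txt \
                 --trials 100 --out screen.csv
kinforage analyze --runs runs
```

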