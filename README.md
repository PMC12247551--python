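# brainstates

Brain-state occupancy analysis for population imaging cohorts.

Cerebral small vessel disease shows up on MRI as white matter
hyperintensities (WMH), and its cognitive consequences have been linked to
*functional network dedifferentiation*: participants with a heavier WMH
burden spend less of their resting-state scan in the brain states dominated
by the default mode network (DMN), and less time in those states goes along
with slower executive performance.  `brainstates` implements that analysis
chain as a tested, reusable Python package for researchers working with
parcel-level resting-state fMRI and lesion segmentations:

* **Co-activation-pattern (CAP) brain states** — pool every participant's
  parcel × time BOLD matrix and cluster the volumes with k-means (k = 5)
  under correlation distance `d(x, y) = 1 − r(x, y)`; per participant, the
  fractional occupancy `FO_{s,i}` of state *s* is the share of volumes
  assigned to it, and `fo_high` is the mean FO of the two highest-occupancy
  states.
* **WMH quantification** — 26-connected components below 30 voxels are
  removed from binary lesion masks; surviving voxels are split into
  periventricular (≤ 10 mm from the ventricular system) and deep (> 10 mm)
  compartments and converted to mL.
* **Occupancy models** — a fixed-dispersion beta regression
  `logit E[fo_high] = β₀ + β_w·ln WMH⁺ + β_z·1{WMH=0} + age + sex`
  (reported as an odds ratio per interquartile ratio of WMH volume), a
  Gamma GLM with log link for TMT-B completion times (reported as a
  multiplier per 5 percentage points of occupancy), and binomial GLMs for
  bounded cognitive scores.
* **Robustness and design tools** — a 9 × 9 × 3 multiverse grid over
  confound-regression variants, parcellations and WMH compartments, and a
  bootstrap power curve over a ladder of sample sizes.
* **A synthetic-cohort generator** with known ground truth (zero-inflated
  log-normal WMH, beta-distributed occupancies linked to log-WMH,
  Gamma-distributed completion times, planted state centroids on seven
  canonical networks), so the whole pipeline is testable without access to
  protected cohort data.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import brainstates as bs
from brainstates import caps, pipeline, synth

# a synthetic cohort with the default study conditions
cfg = bs.GeneratorConfig(n_participants=400, seed=7, n_parcels=60)
cohort, truth, sel, occ = pipeline.cohort_with_occupancy(
    cfg, use_clustering=True, n_restarts=4
)

qc = pipeline.quality_check(occ, sel.top_two)
print(f"separation {100*qc.difference:.1f} pp "
      f"[{100*qc.ci_lower:.1f}, {100*qc.ci_upper:.1f}]")

primary = pipeline.run_primary(cohort)
e = primary.effect
print(f"OR per IQR {e.estimate:.4f} [{e.ci_lower:.4f}, {e.ci_upper:.4f}] "
      f"p={e.pvalue:.3g}")

secondary = pipeline.run_secondary(cohort)
e = secondary.effect
print(f"TMT multiplier per 5 pp {e.estimate:.4f} "
      f"[{e.ci_lower:.4f}, {e.ci_upper:.4f}]")
```

Output:

```
separation 8.8 pp [7.9, 9.7]
OR per IQR 0.9262 [0.8954, 0.9582] p=9.36e-06
TMT multiplier per 5 pp 0.9888 [0.9502, 1.0289]
```

The quality check confirms that the two high-occupancy states are clearly
separated from the other three.  The primary model estimates the change in
odds of occupying a high-occupancy state per Q3/Q1-fold increase in WMH
volume (the generator plants 0.95; at n = 400 the point estimate wanders
but the CI covers it), and the secondary model estimates the multiplicative
change in expected TMT-B time per 5-percentage-point increase in occupancy
(planted: 0.98).

The same steps are available from the shell:

```bash
brainstates simulate --n 400 --seed 7 --out sim/
brainstates states --bold-manifest sim/bold/manifest.tsv --k 5 \
    --restarts 20 --seed 0 --out states/
brainstates fit --cohort sim/cohort.tsv --occupancy states/occupancy.tsv \
    --model primary --out fit/
brainstates multiverse --out multiverse.tsv
brainstates power --cohort sim/cohort.tsv --sizes 200,600,1000,1500 \
    --reps 1000 --seed 0 --out power.tsv
brainstates wmh --mask lesions.nii --ventricles ventricles.nii \
    --cutoff 10 --min-cluster 30 --out wmh.tsv
```

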