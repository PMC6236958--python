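# cscompliance

Patient-specific estimation of how total cranio-spinal compliance (CSC) is
distributed between the cranium and the spinal canal, from one cardiac cycle
of flow waveforms: net transcranial blood flow Q_A−V (arterial inflow minus
venous outflow) as input and cervical CSF flow Q_CSF as output, both in mL/s
at (by default) 32 uniform cardiac phases — the quantities a cine
phase-contrast MRI exam provides. The package is aimed at researchers in CSF
hydrodynamics and non-invasive intracranial pressure who want a transparent,
testable implementation of the lumped-parameter identification approach,
together with a forward simulator and synthetic-cohort generator so every
estimation path can be verified by parameter recovery without MRI data.

## Model

The cranio-spinal system is modelled as a second-order linear circuit with
cranial and spinal flow resistances R_C, R_S, compliances C_C, C_S and the
inertance L_S of the CSF column:

    H(s) = Q_CSF(s)/Q_A−V(s)
         = (s·R_C/L_S + 1/(C_C·L_S)) / (s² + s·(R_C+R_S)/L_S + (1/C_C + 1/C_S)/L_S)

Its dc gain H(0) = C_S/(C_C+C_S) is the spinal share of total compliance —
the target quantity — and is identifiable from flow data alone even though
the five elements individually are not. Pole-zero matched discretization at
the frame interval T gives

    H(z) = (p1·z + p2)/(z² + q1·z + q2),     H(z=1) = H(s=0).

The estimator sweeps all (q1, q2) on a 0.01-step lattice inside the
second-order stability triangle (both poles strictly inside the unit
circle), fits (p1, p2) per pair by ordinary least squares on the difference
equation

    Q_CSF(n) + q1·Q_CSF(n−1) + q2·Q_CSF(n−2) = p1·Q_A−V(n−1) + p2·Q_A−V(n−2)

(lags wrap cyclically over the cardiac cycle), scores each quartet by the
Nash–Sutcliffe efficiency E of its periodic steady-state prediction, keeps
quartets with E > 0.7, histograms their dc gains over 0–100% in 1% bins, and
reports the histogram mode as the spinal compliance contribution (cranial =
100 − spinal). The dc gain of the single best-fitting quartet is reported
alongside; on clean synthetic data it recovers the generating ratio almost
exactly, while the histogram mode is a coarser, deliberately fit-pooled
statistic (see `docs/methods.md` for its accuracy characterisation).

## Worked example

```python
from cscompliance import (DEFAULT_PARAMS, WaveformSpec, generate_subject,
                          estimate_compliance_distribution, csf_stroke_volume)

subject = generate_subject(DEFAULT_PARAMS, WaveformSpec(seed=0))
print("truth spinal share:", subject.truth_spinal_percent, "%")

result = estimate_compliance_distribution(subject.cycle)
print(f"histogram mode:   spinal {result.spinal_percent}% / cranial {result.cranial_percent}%")
print(f"best-fit quartet: gain {100*result.best_fit_gain:.1f}%  (E = {result.best_e:.3f})")
print(f"accepted quartets (E > 0.7): {result.n_accepted}")

caudal, cranial = csf_stroke_volume(subject.cycle.q_csf, subject.cycle.cycle_duration)
print(f"CSF stroke volume: {caudal:.2f} mL/cycle")
```

prints

```
truth spinal share: 75 %
histogram mode:   spinal 49% / cranial 51%
best-fit quartet: gain 76.0%  (E = 1.000)
accepted quartets (E > 0.7): 8637
CSF stroke volume: 0.50 mL/cycle
```

The synthetic subject was generated by a circuit whose true spinal share is
75%. The best-fitting quartet's dc gain (76.0%) recovers it to within one
point. The histogram mode (49%) illustrates the central caveat of the
fit-pooled statistic on noise-free data: with a perfect in-class fit
available (best E = 1.0), more than 8,000 grid quartets clear the 0.7
threshold and the pooled histogram peaks away from the truth; the mode is
informative when the acceptance set is small (as with real, imperfectly
fitting data). The stroke volume (0.50 mL) is the CSF volume displaced into
the spinal canal per heartbeat.

The same workflow is available from a shell:

```
cscompliance simulate --seed 0 -o subject.csv
cscompliance estimate subject.csv --report report.json
cscompliance sensitivity subject.csv
cscompliance cohort <dir> --summary summary.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch: it generates a seeded synthetic
subject, estimates its compliance distribution at both documented grid
steps (0.01, 0.001) and both E thresholds (0.7, 0.6), builds a 12-subject
virtual cohort, and summarises the cohort correlations, writing the
machine-readable results dictionary to `--out`.
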