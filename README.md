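# fearsig

Binary **fear recognition from a reduced set of physiological signals** —
electrocardiogram (ECG, mV), galvanic skin response (GSR, µS) and skin
temperature (SKT, °C) — the three sensors that fit today's wrist-worn
wearables.  The package is aimed at affective-computing researchers who
want a tested, reproducible implementation of the classic windowed
pipeline: segmentation, denoising, a 48-feature linear + non-linear
extractor, PAD-based fear labeling, and subject-dependent /
subject-independent classification, together with a synthetic session
generator so everything can be exercised without access to any
EULA-restricted recording corpus.

## The pipeline

Recordings are organized subject → trial → channel at a common sampling
rate (256 Hz by default).  Each trial carries a SAM self-report (valence
*V*, arousal *A*, dominance *D*, each 1–9).  Processing steps:

1. **Trim** the 30 s neutral recovery padding at both ends of each trial,
   keeping the 60 s stimulus span.
2. **Segment** into 20 s windows with 10 s overlap — five windows per
   trial, window count = ⌊(N − L)/S⌋ + 1 with L = 20·fs, S = 10·fs.  A
   20 s window gives a 0.05 Hz/bin spectral resolution and needs 60 KB of
   32-bit storage for three channels.
3. **Denoise** per sensor: ECG through a linear-phase FIR band-pass
   (0.5–40 Hz) plus automatic gain control before R-peak detection; GSR
   and SKT through FIR low-passes (2 Hz, 1 Hz).
4. **Extract 48 features** per window — 25 ECG, 17 GSR, 6 SKT:
   - ECG: mean IBI and SDNN; waveform band powers (0–0.4 Hz in 0.1 Hz
     steps); LF/MF/HF powers of the 4 Hz-resampled IBI tachogram with MF
     and LF/HF ratios; multiscale sample entropy at scales 1–5; DFA α of
     the waveform and of the IBI series; recurrence quantification (RR,
     DET, LAM, L<sub>max</sub>, diagonal entropy, trapping time) and
     correlation dimension D₂.
   - GSR: SCR count / mean amplitude / mean rise time from trough-to-peak
     detection on the phasic component (moving-median tonic split), raw
     mean, SD, IQR; tonic and phasic band powers and low-band ratio; DFA,
     the six RQA measures, D₂.
   - SKT: mean, SD, skewness, kurtosis, two band powers.
5. **Label**: a trial is *fear* (positive) iff V ≤ 5, A > 5 and D ≤ 5 —
   the low-valence / high-arousal / low-dominance octant of the PAD space;
   all five windows inherit the trial label.
6. **Classify** with SVM, k-NN or boosted trees (ENS), tuned by a
   sequential model-based (Bayesian) optimizer over stratified 5-fold
   misclassification.  Two protocols: per-subject stratified 5-fold
   (subject-dependent) and leave-one-subject-out after per-subject
   z-scoring (subject-independent).  Metrics: ACC, AUC = P(X₁ > X₀),
   Gmean = √(sensitivity·specificity) and F1, aggregated as mean ± MAD.

## Worked example

```bash
fearsig simulate --subjects 3 --trials 10 --fear-frac 0.2 --seed 42 --out demo
fearsig extract  --data demo --out demo/features.csv
fearsig train    --mode dependent --algo ens --budget 10 --seed 42 \
                 --input demo/features.csv --report demo/report.json
```

which prints

```
wrote 3 sessions to demo
wrote 150 feature rows to demo/features.csv
dependent/ens: acc=99.33% (MAD 0.89%), auc=100.00% (MAD 0.00%), gmean=98.05% (MAD 2.60%), f1=97.78% (MAD 2.96%)
```

Three synthetic subjects watch ten 60 s stimuli each (two of them
fear-inducing), padded with 30 s recovery; each trial yields five 20 s
windows, hence 150 feature rows.  The default condition effect (heart
rate up, HRV down, SCR rate doubled, skin temperature down during fear
stimuli) is strong enough that per-subject boosted-tree models separate
the classes almost perfectly; `demo/report.json` holds the per-subject
confusion counts, metrics and chosen hyperparameters.  The same steps are
available as library calls (`fearsig.synthetic.synth_dataset`,
`fearsig.features.extract_feature_table`,
`fearsig.modeling.subject_dependent_eval` / `loso_eval`).

## Limitations

The synthetic generator reproduces the structure and first-order
autonomic correlates of a lab elicitation corpus, not real physiology:
see `docs/methods.md` for what passing tests do and do not demonstrate,
and for every tunable parameter with its default and rationale.
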