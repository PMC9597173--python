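# methkin — post-replication DNA methylation maintenance kinetics

After DNA replication, the nascent strand is unmethylated and DNMT1 copies
parental CpG methylation onto it. Pulse-chase bisulfite experiments
(Repli-BS) observe single-CpG methylation calls at known post-replication
chase times (0, 1, 4 and 16 h), so the *rate* at which each CpG regains
methylation can be inferred — and the way those rates co-vary on neighbouring
CpGs carries a mechanistic signature of how the enzyme works. `methkin`
implements that analysis end to end for scientists studying maintenance
methylation: synthetic data generation, per-CpG rate inference,
distance-resolved correlation functions, stochastic mechanism simulation,
and the decomposition that turns a rate-correlation curve into an estimate
of DNMT1's sliding length on DNA.

## The model

* **Per-site kinetics.** Each CpG *i* is a Poisson (exponential waiting
  time) process: a read of post-replication age τ is methylated with
  probability `f_i (1 − e^{−k_i τ})`, where `k_i` (h⁻¹) is the remethylation
  rate and `f_i ∈ [0,1]` the plateau (bulk) methylation fraction. The 1-h
  labelling pulse makes the age of a read at chase time *t* uniform on
  [t, t+1] h; the likelihood marginalizes this analytically, and `(k_i, f_i)`
  are fitted by maximum likelihood per site.
* **Rate correlation.** For each integer genomic distance *d*, the Pearson
  correlation of `k` over all site pairs exactly *d* bp apart. State
  (methylation-fraction) correlation is computed the same way.
* **Mechanisms.** *Distributive*: the enzyme rebinds each hemimethylated CpG
  independently at rate `k_f` — methylation times are independent, so rates
  are uncorrelated at every distance. *Processive*: after catalysis the
  enzyme can stay on DNA and reach neighbouring targets by 1D diffusion
  (diffusion coefficient `D`, unbinding rate `k_off`). The competition
  between the nearest targets left/right and unbinding is the classical
  splitting problem of diffusion with killing,
  `P_right = sinh(d_L/λ) / sinh((d_L+d_R)/λ)` with sliding length
  `λ = sqrt(D/k_off)`; the probability of reaching a target *d* bp away
  before unbinding is `e^{−d/λ}`, which imprints an exponentially decaying
  rate correlation, `Corr(d) ∝ e^{−d·sqrt(k_off/D)}`.
* **Decomposition.** Observed rate correlation mixes this diffusion-based
  part θ with a region-based part φ carried by slowly varying genomic
  features (bulk methylation q, CpG density r, accessibility s):
  `Total(d) = θ(d) + (1 − θ(d))·φ(d)`. φ is estimated by a cluster-shuffle
  null — k-means on (q, r, s), then permuting positions within clusters —
  and θ is extracted algebraically and fitted with `A·e^{−a·d}`. The decay
  constant estimates `sqrt(k_off/D)`: decay length `1/a` is the sliding
  length, `(1/a)²` is `D/k_off`.

## Worked example

The numbered drivers under `analysis/` run the study end to end on synthetic
data. The headline one simulates a processive enzyme with sliding length
36 bp on 25,000 CpGs, emulates Repli-BS reads (~30 per site), infers rates,
decomposes the rate correlation and fits the exponential:

```
$ python analysis/04_processivity_estimate.py --seed 0
 window_bp  decay_constant_per_bp  decay_length_bp  d_over_koff_bp2  true_sliding_length_bp  n_inferable
       100               0.028271        35.371888           1300.0                    36.0        25000

recovered sliding length 35.4 bp (simulated 36 bp); implied D/k_off ~ 1300 bp^2
```

The fitted decay constant (0.028 bp⁻¹) converts to a sliding length of
~35 bp, recovering the simulated 36 bp, and to `D/k_off ≈ 1300 bp²` at two
significant figures. `analysis/02_mechanism_fingerprint.py` contrasts the
two mechanisms (only the processive one shows short-range rate correlation;
bulk state correlation tracks the input landscape under both), and
`analysis/03_inference_accuracy.py` tabulates rate-estimate error versus
read depth (~30% median relative error at 30 reads/site, vanishing bias at
high depth).

A `methkin` command-line interface exposes the same stages
(`synth`, `simulate`, `infer-rates`, `correlate`, `decompose`, `run-all`)
over plain-text BED/bedGraph/TSV files.

## Layout

```
src/methkin/      synthgen, inference, corrfuncs, mechsim, decompose,
                  io, pipeline, cli
analysis/         numbered study drivers writing tables under results/
tests/            unit, property and end-to-end suites
docs/methods.md   model, estimators, parameter choices, limitations
```
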