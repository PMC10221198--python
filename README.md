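# medpatterns

Latent class and latent transition analysis of binary multimorbidity-medication
indicators, for epidemiologists who use medication exposure ("do you take a
statin: yes/no", across 27 chronic-disease medication categories) as a proxy
for the chronic diseases a cohort carries. The motivating setting is a
two-phase smoker cohort (baseline and five-year follow-up) in which medication
patterns act as multimorbidity patterns: a low-medication class, a
hypertension/cardiovascular + high-cholesterol class, a class adding type-2
diabetes treatment, and a cholesterol-only class.

## The model

**Latent class analysis (LCA).** Each subject's 0/1 response vector
*y&#7522;* over *J* items follows a *K*-component multivariate Bernoulli
mixture with conditional independence given class:

P(y&#7522;) = Σ&#8342; π&#8342; Π&#11388; ρ&#8342;&#11388;^y&#7522;&#11388; (1 − ρ&#8342;&#11388;)^(1−y&#7522;&#11388;)

where π is the class-prevalence vector and ρ the K×J item-response
probability matrix. Fitting is by multi-start EM in log space. Fit is
reported through the deviance G² against the saturated model over observed
response patterns, and the G²-based criteria

- AIC = G² + 2p, BIC = G² + ln(N)·p, CAIC = G² + (ln N + 1)·p,
  SABIC = G² + ln((N+2)/24)·p, with p = K·J + (K − 1) free parameters,
- relative entropy E = 1 − Σ(−p&#7522;&#8342; ln p&#7522;&#8342;)/(N ln K) ∈ [0, 1],

and subjects are modally assigned to their highest-posterior class. Classes
are labeled from their item-response profiles (high if ρ > 0.7, low if
ρ < 0.3; a class with every ρ < 0.06 is "Low medication").

**Latent transition analysis (LTA).** Two phases are joined by an initial
class distribution δ and a K×K Markov transition matrix τ:

P(y⁽¹⁾, y⁽²⁾) = Σ&#8342;&#8321; Σ&#8342;&#8322; δ&#8342;&#8321; τ&#8342;&#8321;&#8342;&#8322; f&#8342;&#8321;(y⁽¹⁾; ρ⁽¹⁾) f&#8342;&#8322;(y⁽²⁾; ρ⁽²⁾)

Longitudinal measurement invariance (ρ⁽¹⁾ = ρ⁽²⁾) is tested by a
likelihood-ratio test with K·J degrees of freedom against the free model;
when it is rejected, patterns are reported per phase. Modal class membership
is finally cross-tabulated between phases and related to self-reported
comorbidity flags by logistic regression.

A seeded generator (`medpatterns.simulate`) draws two-phase panels from a
fully specified truth, including a default scenario that emulates a
COPDGene-like cohort (N = 5564, 27 items, four classes with the published
prevalences, signature response probabilities and transition percentages).

## Worked example

```python
import medpatterns as mp

truth = mp.copdgene_like_truth(n_subjects=5564, seed=1)
d1, d2, c1, c2 = mp.generate_longitudinal(truth)

sel = mp.fit_range(d1, 2, 5, n_starts=10, seed=0, tol=1e-7)
print(sel.table.round(2).to_string(index=False))
print("minimum BIC at K =", sel.best_bic())
```

```
 n_classes  g_squared     aic     bic    caic   sabic  entropy
         2    8435.76 8545.76 8910.08 8965.08 8735.31     0.76
         3    7522.26 7688.26 8238.06 8321.06 7974.31     0.76
         4    7142.14 7364.14 8099.42 8210.42 7746.69     0.80
         5    7076.50 7354.50 8275.25 8414.25 7833.55     0.74
minimum BIC at K = 4
```

BIC bottoms out at the generating four-class structure with entropy 0.80
(≥ 0.8 is read as precise classification). Labeling the four classes and
testing measurement invariance across the phases:

```python
for p in mp.label_classes(sel.fits[4].params, d1.item_names):
    print(f"LC{p.class_index} ({p.prevalence:.1%}): {p.label}")

free = mp.fit_lta(d1, d2, 4, invariant=False, n_starts=2, seed=0)
con  = mp.fit_lta(d1, d2, 4, invariant=True,  n_starts=2, seed=0)
res = mp.invariance_test(free, con)
print(f"invariance LRT: G2_delta={res.g2_delta:.2f}, df={res.df_delta}, p={res.p_value:.3g}")
```

```
LC0 (56.2%): Low medication
LC1 (27.1%): Hychol predominant
LC2 (12.3%): HTN/CVD+Hychol predominant
LC3 (4.3%): HTN/CVD+T2D+Hychol predominant
invariance LRT: G2_delta=921.17, df=108, p=3.54e-129
```

The four generating patterns are recovered and named; because the generating
scenario uses phase-specific response probabilities, measurement invariance
is firmly rejected (p < 0.0001), so patterns would be reported per phase.

The same pipeline runs from the shell:

```sh
medpatterns simulate --n-subjects 5564 --seed 1 --out data/
medpatterns select data/indicators_p1.csv --k-min 2 --k-max 6 --out selection.csv
medpatterns run-all --out results_run --seed 1
```

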