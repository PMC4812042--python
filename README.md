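# qprototype

Hilbert-space interference models for two-concept membership data.

## The problem

When people judge whether items belong to a concept pair and its combination
— say the 24 food items rated against *Fruits*, *Vegetables* and *Fruits or
Vegetables* — the combination weights routinely violate the bounds that any
classical (fuzzy-set / Kolmogorovian) combination rule must satisfy: a
disjunction falls below one or both of its components (underextension), or
exceeds their sum (overextension). `qprototype` is a toolkit for researchers
in mathematical psychology and quantum cognition who want to

1. **diagnose** those violations in a table of membership triples
   (μ_k(A), μ_k(B), μ_k(A or B)),
2. **fit** the complex Hilbert-space model in which each concept is a unit
   vector, the disjunction is their superposition (|A⟩+|B⟩)/√2, and the
   deviations are quantum interference terms,
3. **visualize** the combination as two interfering 2-D Gaussian wave
   packets, and
4. **predict** the fourth conjunction/negation weight from the other three,
   classically and quantum-informed.

## The model

Each measured disjunction probability decomposes as

    μ_k(A or B) = (μ_k(A) + μ_k(B))/2 + c_k √(μ_k(A) μ_k(B)) cos φ_k

with interference phase φ_k and basis overlap c_k ∈ (0, 1]. The magnitude of
φ_k follows from the data by arccos; the signs ε_k are assigned by a greedy
scheme on the *interference budgets* λ_k = √(μ_A μ_B − (μ_AorB − (μ_A+μ_B)/2)²),
ordered descending, that keeps every partial sum S_j ≥ 0 and as small as
possible — this enforces the sine half of the orthogonality constraint
⟨A|B⟩ = 0 (the cosine half is automatic for normalized columns). A single
overlap c_m < 1 on the largest-budget item closes the remaining residual,
and the model lives in ℂ^(n+1): every item spans one basis direction except
item m, which spans two.

The 2-D illustration places the items in a plane where two Gaussian packet
densities (times an effective cell weight δ_eff) reproduce the two
single-concept columns, interpolates the per-item phases with a 24-monomial
polynomial θ(x, y), and renders the superposition density
½(|ψ_A|² + |ψ_B|²) + |ψ_A ψ_B| cos θ(x, y).

## Worked example

```python
>>> import numpy as np, qprototype as qp
>>> table = qp.load_fruits_vegetables()          # packaged 24-item study
>>> est = qp.ConceptDisjunctionHilbert().fit(table)
>>> round(est.s_final_, 4), round(est.c_m_, 4)   # greedy sum, rank-1 overlap
(0.0154, 0.802)
>>> est.items_[est.m_index_]                     # largest interference budget
'Tomato'
>>> round(est.phi_deg_[0], 1)                    # Almond's phase, degrees
84.0
>>> float(np.abs(est.predict() - table.mu_AorB).max())  # exact reconstruction
1.3877787807814457e-17
>>> est.orthogonality().overlap_abs < 5e-4       # |<A|B>| ~ input rounding
True
```

`est.s_final_` is the final greedy partial sum of the signed interference
budgets (0.0154: small but nonzero because the printed columns carry
4-decimal rounding), `est.c_m_` the basis overlap of *Tomato* that closes
the orthogonality constraint, and `predict()` returns the disjunction
column implied by the fitted phases — identical to the input by
construction. The estimators follow scikit-learn conventions
(`get_params`/`set_params`, fitted attributes with trailing underscores).

The same pipeline from the shell:

```
qproto build table1.csv -o model.json      # fit + serialize the model
qproto diagnose table1.csv                 # per-item classicality labels
qproto wavefield table1.csv --outdir wf/   # phase field + 3 density PNGs
qproto predict weights.csv                 # negation predictions, I statistic
qproto simulate --regime quantum --seed 1  # synthetic table, known phases
```

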