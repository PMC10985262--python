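# danpkit

DEMATEL-based ANP (DANP) analysis of expert influence panels: total-influence
matrices, cause/effect network maps, and limiting supermatrix weights.

## What problem this solves

Multi-criteria decision analysis often starts from a panel of experts who rate,
on an integer 0–4 scale, how strongly each factor in a system influences every
other factor. The DEMATEL method (Decision-Making Trial and Evaluation
Laboratory) turns those ratings into a *total-influence* matrix that
accumulates direct and all indirect influence, separating factors into a
**cause group** (net influencers — the levers to act on) and an **effect
group** (net influenced). The DANP extension feeds that same matrix into an
Analytic Network Process supermatrix, whose limiting power yields a global
**influence weight** for every factor — the priorities a decision-maker should
attend to.

`danpkit` implements this pipeline for factor systems organised as dimensions
containing criteria (the bundled example is a mental-health factor model for
hospital staff working from home: 3 dimensions, 18 criteria). Because raw
questionnaire matrices from such surveys are rarely published, the package
includes a synthetic panel generator with a known ground truth, so every stage
can be validated end-to-end.

## The model

With `ϑ` experts rating `n` criteria, the stages are:

1. **Aggregate** — direct-influence matrix `A = (1/ϑ) Σ_ε E^ε` (entrywise mean
   of expert matrices, zero diagonal).
2. **Normalize** — `δ = max(max row sum, max column sum)` of `A`;
   `D = A / δ`.
3. **Total influence** — `T = D + D² + ⋯ = D (I − D)⁻¹`, finite because the
   spectral radius of `D` is below 1.
4. **Indices** — give `uᵢ = Σⱼ tᵢⱼ`, receive `rᵢ = Σᵢ tᵢⱼ`, influence center
   `uᵢ + rᵢ`, net cause/effect `uᵢ − rᵢ` (positive ⇒ cause group). Applied to
   `T` for criteria and to the block means `T_D` for dimensions. The INRM
   (influential network relation map) plots factors at `(u + r, u − r)` with
   arrows for influences above a threshold (default: mean off-diagonal of the
   matrix in use).
5. **Supermatrices** — unweighted `W = (T^α)ᵀ` (each row segment of each
   dimension block of `T` normalised to sum 1, then transposed); weighted
   `V` scales each block of `W` by the transposed row-normalised `T_D`, making
   every column of `V` stochastic.
6. **Limiting weights** — `ϖ* = lim_ρ V^ρ`; the common column is the global
   weight vector. Dimension weights are sums of member criteria's global
   weights; local weights renormalise within a dimension, so
   `global = dimension × local` holds exactly.

A panel-stability statistic accompanies the run: the **consensus gap**, the
mean absolute relative change of `A` when the most recently added expert is
removed (below 5% is conventionally read as consensus; `1 − gap` is the
quoted confidence level).

## Worked example

```python
import danpkit as dk

spec = dk.study_panel_spec(seed=42)          # 33 experts, 18 criteria, noise sd 0.5
panel = dk.sample_panel(spec)
result = dk.run_pipeline(spec.system, panel)

top = result.weights.criteria.sort_values("global_rank").head(3)
print(top[["global_weight", "global_rank"]].round(3))
print("cause group:", ", ".join(sorted(result.criteria_indices.query("group == 'cause'").index)))
print(f"consensus gap {result.consensus.gap:.4f} -> confidence {100 * result.consensus.confidence:.2f}%")
```

prints

```
        global_weight  global_rank
factor
C35             0.067            1
C34             0.067            2
C33             0.066            3

cause group: C14, C16, C17, C25, C26, C32, C33, C35
consensus gap 0.0052 -> confidence 99.48%
```

The three highest global weights identify the criteria most involved in the
influence network (here communication-issues criteria, led by "a lack of
coordination", C35); the cause group lists the net drivers — by construction
of this synthetic panel, exactly the criteria whose outgoing influence was
elevated in the ground truth; and the consensus gap certifies that removing
the last respondent changes the aggregate matrix by about half a percent.

The same run from a shell:

```sh
danp simulate --out panel/ --seed 42
danp run --panel panel/ --out results/
```

which writes `indices.csv`, `weights.csv`, `consensus.json`, INRM node/edge
tables and DOT files, a full-precision `matrices.json` audit, and a rounded
plain-text `report.txt`. `danp dematel`, `danp danp` and `danp inrm` run
single stages.

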