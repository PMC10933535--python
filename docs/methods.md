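# Methods

## Model structure

`gliorfba` couples two formalisms. The metabolic layer is a multicellular
constraint-based model: metabolites and reactions carry cell tags (glioma
`_c`/`_C`, T-cell `_T`, macrophage `_M1`/`_M2`) and all cross-feeding goes
through shared extracellular (`_EXT`) species; a flux vector must satisfy
steady-state mass balance `S v = 0` within per-reaction bounds, and a
linear objective is maximized with scipy's HiGHS interface. The signalling
layer is a synchronous Boolean network in which rule leaves may be
threshold predicates on *metabolite pools* — named concentrations (mM)
that bridge the two layers. Regulation runs in both directions:
pools feed predicates (metabolism → signalling), and regulatory links
switch reaction bounds off while a Boolean controller is active
(signalling → metabolism; the bundled link blocks T-cell fatty-acid
transport while AMPK_T is on).

### Time scales

Metabolism is fast, transcriptional regulation slow. One regulatory tick
(`dt_reg = 1`) comprises: read pools → one synchronous Boolean step →
derive the bounds overlay from the links → `floor(dt_reg/dt_met) = 14`
metabolic ticks (`dt_met = 0.07`), each solving the LP under the current
overlay and integrating every pool by
`conc ← max(0, conc + pool_scale · dt_met · Σ sign·flux)` over its coupled
reactions. The 0.02 remainder of 1/0.07 is dropped. Reads-then-acts
ordering avoids same-tick circularity between the layers. Negative
concentrations clamp to zero and are logged as events. Default runs last
`n_steps = 2000` regulatory ticks, i.e. 28 000 metabolic ticks.

### Degeneracy and determinism

Flux polytopes have alternate optima, and the framework's outputs are flux
*trajectories*, so a deterministic representative matters. After the
primary solve the objective is pinned at its optimum (two-sided, relative
tolerance 1e-9) and the total absolute flux is minimized via the standard
split-variable formulation. Only flux signs and qualitative orderings are
treated as meaningful; the exact degenerate representative is a numerical
convention. Solver feasibility tolerance is 1e-9; solution verification
(`check_solution`) demands `max |S v| ≤ 1e-6` and bound satisfaction to
the same tolerance.

Within a regulatory tick the bounds do not change, so the 14 metabolic
LPs are identical programs; across ticks they repeat whenever the overlay
state repeats. `FbaSolver` therefore memoizes on (objective, effective
bounds): `n_calls` counts FBA solves as posed (28 000 per default run)
while `n_lp_solves` counts distinct LP factorizations (typically a
handful). This is purely an implementation detail — the returned solution
for a cached key is bitwise the solution of that tick's LP.

### Bound-precedence rules

Three sources of bounds compose in a fixed order: perturbation edits
rewrite the model itself and take precedence over the condition overlay
for the edited reactions (otherwise a condition entry could silently
re-open a blocked transporter); the condition overlay replaces model
defaults; a firing regulatory link replaces the condition's entry for its
target (the switch governs the reaction outright — necessary because the
glioma condition *forces* a basal fatty-acid import that the AMPK link
must be able to zero). Multiple links on one reaction intersect
(tightest bounds win).

## The rule grammar

Rules are `NODE = expression` with `&`, `|`, `not(...)`/`!`, round and
square brackets interchangeable as grouping, and predicates `ID > NUM` /
`ID >= NUM` (the identifier may itself be parenthesised). Precedence is
NOT > AND > OR; `>=` is true exactly at the threshold, `>` is not; `<`
and `<=` are rejected explicitly. One published rule contains a stray
unmatched closing bracket; since bracket kinds are synonyms, balance
reduces to depth counting, and a closer with no outstanding opener is
dropped with a warning rather than silently guessed around. The parser is
a small hand-written recursive-descent implementation; serialization
parenthesizes nested same-operator groups so `parse(serialize(e))` is the
structural identity.

## The exemplar model

The full published reconstruction (326 reactions, 357 metabolites, 192
signalling molecules) ships only as supplementary spreadsheets, so the
package bundles a reduced surrogate (~100 reactions, seed-free and
bit-stable) that encodes every printed equation and bound convention and
reproduces the study's qualitative regimes. Per cell it contains lumped
glycolysis, lactate dehydrogenase and export, pyruvate dehydrogenase
(PYDH) plus an abridged TCA cycle, an electron-transport lump feeding the
printed ATP-synthase stoichiometry, an ATP-maintenance demand, fatty-acid
transport and oxidation, glutamine/glutamate handling (including the
glioma xCT antiporter and glutathione synthesis), an arginine branch (NOS
vs arginase), and a ROS branch (glutathione scavenging vs SOD/catalase).

Deliberate stoichiometric choices, each load-bearing:

* **Cytosolic vs mitochondrial NADH.** Glycolysis produces cytosolic
  NADH that only lactate dehydrogenase (or an explicitly opened
  malate–aspartate shuttle lump) can clear. This ties glycolysis to
  lactate export in every cell whose shuttle is closed, and prevents
  glucose from covertly fuelling oxidative ATP — which is what forces the
  T-cell onto glutamate (baseline), fatty acid (glutamate block) or
  arginine (AMPK scenario) for its mitochondrial budget. Only the
  astrocyte condition opens the glial shuttle (full oxidation, no lactate).
* **Proton bookkeeping.** The ATP-synthase column keeps side-specific
  proton species (4 H_in consumed, 3 H_out produced) so the column cannot
  self-cancel; the electron-transport lump supplies H_in and sinks absorb
  H_out/H₂O.
* **ROS is a dead end.** The SOD/catalase and glutathione-peroxidase
  lumps do not regenerate molecular oxygen; allowing that would let the
  LP convert waste ROS into respiratory O₂.
* **Glutamate accumulation.** A storage overflow (`GLUstore_c`,
  producing 0.5 ROS per glutamate) gives the glioma a disposal route for
  forced glutamine influx once export routes close; this is the lumped
  mechanism behind the SOD rise after the glutamate block.
* **Fuel hierarchy by cost.** Arginine catabolism carries a 1-ATP
  activation cost and glutathione synthesis a 4-ATP lump cost. The former
  makes arginine the fuel of last resort (used only when AMPK has shut
  fatty-acid transport); the latter couples the glioma's glucose draw to
  its growth state, which is what orders the glucose-pool crossings
  across scenarios.
* **Pyruvate overflow valve.** The T-cell can vent cataplerotic pyruvate
  (`PYRex_T`), letting it fully oxidize anaplerotic fuels without
  providing any route that would feed the tumour objective.

Condition-specific bounds (surrogate values standing in for the published
per-condition restrictions) distinguish tumour dominance from the normal
astrocyte state: under glioma dominance PYDH, complex IV, glutamate
dehydrogenase and succinate→OAA regeneration are restricted while xCT,
FAO and forced glutamine uptake are open, and the immune cells are
nutrient-capped; the astrocyte condition inverts these, closes xCT and
fatty-acid import, and re-opens glutamate uptake.

### Pools and gains

Pools model *availability to the immune cells*, not closed mass balance
(a pool tied to a balanced boundary exchange would be constant by
construction). Each couples to the flux that erodes or builds it, with a
per-pool gain folded into the coupling sign and a global
`pool_scale = 8e-4` chosen so threshold crossings spread over hundreds of
regulatory ticks — the slow transcriptional time base:

| pool | init (mM) | threshold | coupling |
|------|-----------|-----------|----------|
| Glucose_T | 1.0 | 0.5 | −1.5 × glial glucose uptake |
| Glutamine_T | 1.0 | 0.5 | −2.5 × glial glutamine uptake |
| Arginine_T | 0.5 | 0.02 | −6 × T-cell arginine catabolism |
| Lactate_T | 2.6 | 3 | +1.2 × glial lactate export |
| FattyAcid_T | 0.5 | 1 | +14.2 × T-cell fatty-acid import |
| Succinate_M1 | 1.0 | 1 | +1 × macrophage succinate export |

Initial values are surrogate basal concentrations, not literature
measurements; they are written into the bundle (`pools.tsv`) for
inspection and editing.

### The marker layer

Around the six published regulatory rules the exemplar adds a minimal
marker layer: `T_bet_T = mTORC1_T & CD28_T` (Th1),
`Gata3_T = CD28_T & !T_bet_T` (Th2),
`FoxP3_T = PD_1_T & !mTORC1_T & (FattyAcid_T > 1) | TGF_b_T` (Treg),
`ARG1_M2 = STAT6_M2 & (Arginine_T > 0.02)` (M2), and `Pa_T = AMPK_T`.
The fatty-acid gate on FoxP3 encodes the Treg lineage's known dependence
on fatty-acid oxidation; mechanistically it is what distinguishes the
AMPK scenario — before AMPK first fires, that scenario is identical to
the plain glutamate block by construction, so any Treg-onset difference
must arise from a signal the AMPK link itself controls. When the link
shuts fatty-acid transport, the FattyAcid_T pool freezes below its
threshold and the Treg program never engages within the horizon, which is
how "Treg onset latest of all scenarios" is realized. Input-node states
(checkpoint and co-stimulation inputs, NF-κB, STAT6) differ between the
glioma and astrocyte conditions and stand in for the published
input-state table.

## What passing tests do and do not show

The exemplar is a surrogate: its solver-facing behaviour (LP optima,
Boolean dynamics, scheduler bookkeeping) is checked against independent
oracles and holds for any model; its *biological* content is calibrated
so that the qualitative regime structure — flux signs and orderings,
phenotype fractions and onsets across the four scenarios — matches the
study's reported directions. Passing the qualitative panel shows the
framework can express and reproduce that regime structure, not that the
reduced network quantitatively represents glioma biology. Absolute flux
values are in arbitrary units throughout.

## Known limitations

* Pools are availability proxies with hand-chosen gains; no physical
  volume or exchange kinetics are modelled.
* No subcellular compartmentalization beyond the cytosolic/mitochondrial
  NADH distinction; all other cofactors are lumped or omitted.
* Perturbations target immune cells only; glioma-side interventions and
  per-molecule signalling delays are out of scope.
* Boolean dynamics are synchronous and deterministic; asynchronous
  schemes and attractor basins are not implemented.
* The succinate/OAA scenario's published numeric rescaling is unknown;
  the default closes the outward OAA exchange and halves the succinate
  exchange stoichiometry, with the factor exposed.
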