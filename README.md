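# logictrain

Train context-specific logic models of protein signaling networks against
perturbation (phospho)proteomic data.

Signaling knowledge accumulated in databases and literature is static: a
*prior knowledge network* (PKN) of signed, directed interactions says what
*could* happen, not what happens in a given cell type under given cues.
`logictrain` turns a PKN plus a perturbation screen (stimuli and kinase
inhibitors applied in combination, phosphoprotein readouts measured over
time) into an executable, context-specific logic model, for systems
biologists who have such screens and want mechanistic, predictive models
rather than correlation networks.

## Method

1. **Import.** The PKN is read from a SIF file (`source sign target` rows);
   measurements from a MIDAS CSV (`TR:` treatment columns, one `DA:`/`DV:`
   time/value column pair per readout). Raw values are normalised to [0, 1]
   via a fold change relative to the pre-perturbation baseline, a Hill
   transform, and a penalty for signals close to background — the data is
   *not* discretised.
2. **Preprocessing.** Species that no cue can influence or that cannot
   influence any readout are pruned; unmeasured, unperturbed pass-through
   species are compressed away (signs multiply along the bypass; removals
   that would create a self-loop, contradict an existing edge, or distribute
   a negation over an OR are skipped). Each node's remaining inputs are
   expanded into candidate gates: one single-input gate per edge plus AND
   gates over input pairs. OR is implicit — co-selecting gates with the
   same target ORs them — so inputs B, C into A yield the three hyperedges
   {B→A}, {C→A}, {B∧C→A}, covering the four Boolean wiring options.
3. **Training.** A candidate model is a bitstring P over the scaffold's r
   gates. A seeded genetic algorithm minimises the bipartite objective

       θ(P) = θ_f(P) + α · θ_s(P)
       θ_f  = (1/n_g) Σ_k Σ_l Σ_t (B^M_{k,l,t} − B^E_{k,l,t})²
       θ_s  = (1/v_es) Σ_e v_e P_e

   (mean squared deviation between model and data over all matched
   condition/readout/time points, plus a size penalty counting the inputs
   v_e of each selected gate, normalised by the scaffold total v_es).
   Every evaluated model is archived; the models within a relative
   tolerance of the optimum form a *family*, reported through per-gate
   selection frequencies.
4. **Formalisms.** One simulation engine per data regime, all sharing the
   same scaffold and objective:
   - `bool-ss` — synchronous Boolean updates to a pseudo-steady state
     (oscillating nodes are flagged and penalised as mismatches);
   - `bool-2t` — two pseudo-steady states: after training at τ1, a second
     search over the remaining gates is scored at τ2, simulating from the
     τ1 state with the targets of newly selected gates locked (this is how
     a slow negative feedback can switch a node off permanently);
   - `dt` — Boolean time-course fitting with a single time-scale factor δ
     mapping update steps to data time;
   - `fuzzy` — constrained fuzzy logic: continuous states through a menu of
     normalized Hill transfer functions (AND = min, OR = max), with
     continuous refinement and greedy reduction after the discrete search;
   - `ode` — logic-derived ODEs ẋ_i = (B̄_i(x) − x_i)/τ_i, where B̄_i is a
     smooth relaxation of the Boolean update that agrees with it at 0/1
     vertices; transfer parameters and time constants are fitted to time
     courses.

## Worked example

The package ships a self-contained toy study: a 13-species EGF/TNFa network
whose simulated data plant three behaviours — transient ERK (slow negative
feedback), sustained nfkb oscillations (three-step inhibitor-synthesis
loop), and partial p38 activation (induced-phosphatase brake).

```
$ logictrain toy --outdir toy --seed 0
$ logictrain train toy/toy_pkn.sif toy/toy_data.csv \
    --formalism bool-ss --time-index 2 --already-normalized \
    --outdir run --generations 60 --stall 30
{
 "formalism": "bool-ss",
 "seed": 0,
 "scaffold_gates": 22,
 "scaffold_inputs": 30.0,
 "theta": 0.08188057001566387,
 "theta_f": 0.08174723668233054,
 "theta_s": 0.13333333333333333
}
```

The 17-edge PKN compresses to 10 interactions over 9 species and expands to
a 22-gate scaffold (30 gate inputs in total). The Boolean steady-state fit
reaches θ_f ≈ 0.082: it recovers the EGF→ras→ERK and TNFa→p38 paths but —
being a single-steady-state description — cannot represent the ERK
transient, the nfkb oscillation, or the partial p38 level, which is exactly
the residual left in θ_f. Training the same data with `--formalism bool-2t`
selects the EGF∧¬ERK feedback gate at τ2 (selection frequency 1.0 in the
reported family); `dt` additionally fits the nfkb oscillation; `fuzzy`
drops θ_f by an order of magnitude by fitting the partial p38 level with a
sub-unit transfer gain; `ode` reproduces all three behaviours.

`run/` contains the normalized data copy, the scaffold (extended SIF +
JSON), the evaluated-model archive, gate selection frequencies, the best
model as SIF, fit plots with goodness-of-fit shading, a JSON score summary
and a reproducibility manifest.

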