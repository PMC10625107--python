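# apscreen

Screening of self-assembling oligopeptides by aggregation propensity.

Short peptides (≤ 10 residues) that self-assemble into ordered
nanostructures are valuable building blocks for hydrogels, drug-delivery
vehicles and biosensors, but the sequence space is enormous: 20⁵ = 3.2
million pentapeptides, 20¹⁰ decapeptides, and over 10¹³ sequences once
two-component pentapeptide mixtures are counted. Simulating each candidate
with coarse-grained molecular dynamics (CGMD) is intractable at that scale.
`apscreen` implements the coupled simulation/deep-learning screening stack
for this problem:

* **Aggregation propensity (AP)** — the ratio of solvent-accessible surface
  area at the start and end of a simulation, AP = SASA_initial/SASA_final;
  AP > 1 means surface burial, i.e. aggregation.
* **Hydrophilicity (logP)** — the Wimley–White whole-residue water→octanol
  transfer free-energy sum, logP = Σᵢ ΔG_woct,i (kcal/mol), min–max
  normalized per length to logP′ ∈ [0, 1].
* **Hydrophilicity-corrected scores** — AP_H²⁻⁰·⁵ = AP′² · √logP′, which
  biases selection toward soluble aggregators, and
  AP_HC = AP_H²⁻⁰·⁵ · exp(−(logP′ − μ)²/(2σ²)) with (μ, σ²) =
  (0.4113, 0.0657), which additionally penalizes the insoluble extreme —
  the score that separates hydrogel-forming aggregation from precipitation.
* **Transformer regression network (TRN)** — token embedding + positional
  encoding + self-attention encoder blocks + MLP decoder, trained to
  predict AP from sequence (single chains, placeholder-padded short
  chains, and `PEN1+PEN2` mixtures with a dedicated `+` token and swap
  augmentation). Implemented in pure numpy with hand-written
  backpropagation; no deep-learning framework required.
* **Sequence-space tools** — Latin Hypercube sampling with exact
  per-position stratification, lexicographic enumeration, tokenization.
* **Synthetic CGMD surrogate** — a seeded, deterministic-plus-noise AP
  oracle with planted residue/position structure, aromatic-adjacency and
  charge-complementarity effects, so the whole pipeline (sampling →
  labelling → training → prediction → analysis) runs and is testable
  offline at desk scale.
* **Aggregation laws & transferability** — AP′ quartile-range partition
  (A–D), per-range amino-acid composition tables, and the
  AP_avepen / AP_deca / AP_mixpen comparison that identifies peptide pairs
  whose concatenation or mixing aggregates far better than their
  constituents (opposite net side-chain charges, salt-bridge driven).

## Worked example

```python
>>> from apscreen import logp, logp_normalized, ap_h, ap_hc, net_side_chain_charge
>>> round(logp("NRMMR"), 2)            # kcal/mol, Wimley-White octanol sum
3.13
>>> round(logp_normalized("NRMMR"), 3) # normalized by length-5 extremes
0.474
>>> round(logp_normalized("DMGID"), 3)
0.597
>>> net_side_chain_charge("NRMMR"), net_side_chain_charge("DMGID")
(2, -2)
>>> round(ap_h(0.8, 0.25), 3)          # AP'^2 * sqrt(logP')
0.32
>>> round(ap_hc(0.8, 0.25), 3)         # Gaussian-penalized toward mu=0.4113
0.263
```

NRMMR (net charge +2) and DMGID (net charge −2) are weak aggregators on
their own (simulated AP ≈ 1.15), but their concatenation and equimolar
mixture score AP ≈ 1.6 — the opposite-charge transfer gain the
`agglaws.transfer_analysis` report quantifies.

An end-to-end demo (sample → surrogate labels → train scaled TRN →
predict → range/composition/transfer reports):

```bash
apscreen run --out demo/ --seed 0 --n-train 2000 --preset scaled
```

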