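# fragscore

Toolkit for discovering and validating protein interaction interfaces —
domain–motif interactions (DMIs) and domain–domain interactions (DDIs) — from
the outputs of a protein structure-prediction engine, together with the
experimental (BRET) readout used to validate predicted interfaces. The
prediction engine itself is an external black box: fragscore designs its
inputs and scores, evaluates and benchmarks its outputs.

It is aimed at structural bioinformaticians who want to find the binding
interface hidden inside a known protein–protein interaction: short linear
motifs (SLiMs) sit in intrinsically disordered regions and are routinely
missed when full-length sequences are fed to a predictor, but become
predictable when the disordered regions are cut into small overlapping
fragments and paired with the folded domains of the partner protein.

## What it computes

**Fragment design** (`fragmenter`). Disordered regions are tiled with sliding
windows of sizes 10, 20 and 30 residues; a second window series offset by
half a window guarantees that every candidate motif appears intact in at
least one fragment. Disordered material of protein A is paired with the
ordered regions of protein B and vice versa, plus the ordered×ordered pair.
Extension schedules grow a minimal motif by ±n, ±2n, ±4n, ±6n residues
(n = motif length), then to the neighbouring domains, then to full length;
steps adding <20 residues on both termini are excluded.

**Interface confidence** (`iface_metrics`). A residue is interfacial when any
heavy atom is strictly closer than 5 Å to the partner chain. Metrics per
model: motif-chain / domain-chain interface pLDDT (mean per-residue pLDDT of
a chain's interface residues; pLDDT is read from the PDB B-factor column),
average interface pLDDT (pooled), residue–residue and atom–atom contact
counts, model confidence = 0.8·ipTM + 0.2·pTM, pDockQ (sigmoid of mean
interface pLDDT × ln Cβ-contact count at 8 Å), and iPAE (median predicted
aligned error over residue pairs in contact at 3.5 Å). A model is called
highly confident when the disordered fragment's interface pLDDT ≥ 70 (DMIs)
or the average interface pLDDT ≥ 70 (DDIs, optionally 75 and/or model
confidence ≥ 0.7).

**Evaluation against native structures** (`evaluator`). Model and native are
superposed on the domain chain (all-heavy-atom Kabsch fit, strict atom-name
matching, no outlier rejection); the all-atom motif RMSD in that frame sets
the accuracy category: ≤2 Å correct sidechain, ≤5 Å correct backbone
(= "accurate"), ≤15 Å correct pocket, >15 Å wrong pocket. DockQ
(fnat, iRMS, LRMS; classes incorrect <0.23 ≤ acceptable <0.49 ≤ medium
<0.80 ≤ high) and the mean pairwise DockQ among the top-5 models are also
provided, as is the log2 fold change of motif RMSD across extension steps.

**Reference sets** (`refsets`). Negative controls by Miyata-distance
mutagenesis (key = non-wildcard regex positions of the motif class; each
mutated residue is replaced by its maximally dissimilar amino acid in the
volume/polarity plane) and by cognate-avoiding shuffled domain–motif
pairings. Gap-free global-alignment sequence identity for redundancy checks.

**Benchmark statistics** (`benchstats`). ROC and PR curves, AUROC/AUPRC,
Youden-optimal cutoffs, and the fragmentation summary: per-PPI sensitivity
(positive pairs with a confident *and* accurate model) and false-positive
rate (random pairs with any confident model).

**BRET analysis** (`bret`). Corrected BRET (test ratio minus the maximal
single-tag control), the three-threshold detection rule (cBRET ≥ 0.05,
fluorescence ≥ 500, total luminescence ≥ 50 000), and donor-saturation
titration fits of BRET = (A/D)·BRETmax / (BRET50 + A/D) with residual-
variance-scaled standard errors.

**Synthetic fixtures** (`synthkit`). Deterministic toy complexes (rigid
backbone traces whose model motif is displaced by a prescribed vector, so
the expected motif RMSD is the displacement norm), Gaussian benchmark score
sets, and noisy titrations.

## Worked example

```python
import fragscore as fs

spec = fs.SyntheticComplexSpec(displacement=(1.2, 1.6, 0.0))  # |v| = 2 Å
native, model, scores = fs.make_complex_pair(spec)
mapping = fs.ChainMapping("A", "A", "B", "B")

result = fs.evaluate_model(model, native, mapping)
print(result.rmsd, result.category, result.accurate)
# 2.000000000000001 correct_sidechain True

report = fs.compute_report(model, scores)
print(report.chain_interface_plddt, report.model_confidence)
# {'A': 90.0, 'B': 80.0} 0.88
```

The motif chain of the model copy is rigidly displaced by a vector of norm
2 Å, and the evaluator recovers exactly that RMSD after domain superposition
— the boundary of the correct-sidechain category. The motif-chain interface
pLDDT (80) exceeds the ≥70 cutoff, so this model would be called highly
confident. The same flows are available from the shell:

```sh
fragscore simulate complex --out-dir cx --displacement 1.2,1.6,0
fragscore evaluate --model cx/synthetic_model.pdb --native cx/synthetic_native.pdb --out eval.tsv
fragscore score --model cx/synthetic_model.pdb --scores cx/synthetic_scores.json \
    --disordered-chain B --out metrics.tsv
```

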