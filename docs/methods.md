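# Methods

## Model and assumptions

`stpra` analyses coherent fault trees: a single top event over n-ary AND/OR
gates and basic events (risk factors), with the structure function monotone
in every input. Basic events are mutually independent Bernoulli variables —
the standard ST-PRA assumption, and the one under which the gate formulas
(product for AND, complement-product "overlap subtracted" for OR) are
exact. No dependence or common-cause modelling is attempted, no dynamic
gates (PAND/SPARE), and no exposure-time dependence: probabilities are
per-episode occurrence probabilities, not rates.

A basic event may feed several gates (*repeated event*). Gates are n-ary;
the two-input phrasing common in elicitation materials is a special case. A
one-input gate is accepted with a validation warning, since intermediate
editing states need it; a zero-input gate is an error.

*Underdeveloped* events — factors the elicitation flagged as insufficiently
characterised for decomposition — are ordinary evaluable leaves; the flag
is carried through to every report so readers can see which contributions
rest on thin evidence.

## Probability aggregation

Each risk factor carries a list of elicited sources (value, provenance,
citation). Literature sources shadow expert sources: expert values are used
only when no literature value exists, mirroring elicitation practice where
the literature is considered the more reliable estimate. With the chosen
values V:

- average = mean(V)
- low = mean(V with one instance of max(V) removed)
- high = mean(V with one instance of min(V) removed)

Ties remove exactly one instance ("the highest reported value" is
singular). |V| = 1 collapses all three to the value; empty V leaves the
event unestimated. Derived values are recomputed on every load and never
trusted from files, so the rule has a single implementation. The ordering
low ≤ average ≤ high follows from the rule; a numerical guard clamps
float-noise inversions (~1e-17) rather than letting them surface as
validation failures.

Unestimated events block probability work with an explicit error;
`prune_unestimated` removes them the way the elicitation protocol did
(factors with no assignable probability are dropped), refusing to drop an
AND conjunct, since that would silently weaken the failure condition.

## Cut sets

Minimal cut sets are enumerated by top-down MOCUS expansion. Rows are sets
(idempotence applied eagerly, so a repeated event collapses within a row);
an OR gate branches a row, an AND gate extends it; a final absorption pass
removes supersets. Determinism: gates inside a row are expanded in id
order, gate inputs in declared order, and the output is sorted by
descending probability with lexicographic id tie-breaks, so outputs are
byte-stable. `max_order` truncation is applied after minimisation —
truncating first could delete a low-order set's absorber and leave a
non-minimal survivor. A configurable row cap (default 10^6) turns
combinatorial explosion into a clear resource error rather than an
apparent hang.

`is_cut_set` / `is_minimal` evaluate the structure function directly and
serve as the in-package oracle; the test suite additionally compares MOCUS
against full 2^n truth-table enumeration on trees with ≤ 12 events.

## Exact probability and approximations

Repeat-free (sub)trees are evaluated bottom-up with the gate formulas.
When any event reaches the top along more than one path (detected by path
counting, which also covers shared gate subtrees), the engine pivots by
Shannon decomposition on the most frequently repeated event, ties broken
by id — a deterministic pivot order keeps rounding reproducible. Pivoting
was chosen over inclusion–exclusion across cut sets because elicited trees
have few repeats, making the recursion shallow, and factoring is
numerically stable (no alternating sums).

Alongside the exact value the engine reports the rare-event sum Σ P(Cᵢ)
(unclamped, flagged when > 1 so the approximation's breakdown stays
visible) and the min-cut upper bound MCUB = 1 − ∏(1 − P(Cᵢ)); for coherent
trees with independent leaves, exact ≤ MCUB ≤ min(rare-event sum, 1).
Comparisons in tests use 1e-12 absolute tolerance; reported values keep
full float precision, with 6-decimal formatting only in human-readable
output.

The Monte Carlo oracle draws joint leaf assignments (numpy PCG64, chunked
at 200k draws) and evaluates gates vectorised in dependency order; it
returns the estimate with a normal-approximation 95% half-width and is
reproducible for a fixed seed.

## Importance measures

Birnbaum importance is computed by pinning (Q(p_e=1) − Q(p_e=0)), which is
exact because the structure polynomial is multilinear. Criticality
importance B_e·p_e/Q is the headline per-factor measure — it is the
definition commercial PRA tools report under the name "criticality" — and
Fussell–Vesely is always co-reported, since the verbal reading "probability
that the outcome is a result of this factor" is closer to FV. Reports label
both.

The FV numerator P(∪ cut sets containing e) is computed exactly by a
dedicated monotone-DNF routine: Shannon decomposition over the set family,
pivoting on the most frequent member, with absorption after every pivot
and memoisation on the reduced family. A naive OR-of-ANDs tree over the
cut sets makes every member a repeated event and drives the generic
factoring engine exponential even on the 24-leaf packaged model; the
family-level recursion collapses the product-structured families that
AND-of-OR architectures produce. Exact monotone-DNF probability is #P-hard
in general, so adversarial inputs remain exponential — at this package's
model sizes (hundreds to ~1200 cut sets) it runs in milliseconds.

Importance requires Q > 0; a zero-probability top event raises a
degenerate-model error rather than returning NaNs.

## Sensitivity analyses

`bound_analysis` re-runs the exact engine under the low/average/high
selectors; coherence makes the three rows monotone. `leave_out_analysis`
removes named factor groups via `exclude_events` and reports absolute
deltas against the baseline (probabilities, not relative risks, are the
quantity elicitation stakeholders discuss). Exclusion semantics: OR
parents drop the leaf, emptied OR gates cascade upward; an AND parent
either blocks the exclusion (`forbid`, the default — removing a conjunct
changes the failure logic) or keeps the leaf pinned at probability 1
(`neutralize`, an always-true conjunct). A cascade that would delete a
*gate* input of an AND gate raises under both policies: "keep at 1" has no
defined meaning for a subtree whose factors were declared absent.

## The packaged seclusion-falls model

The shipped fixture reconstructs the published critical-path architecture
of a fall in a psychiatric seclusion room: TOP = AND(disorder, mechanism,
reason, prevention-failure) with prevention-failure = AND(risk-assessment
failure, intervention failure) — exactly two AND gates — and OR branches
naming the published disorders (schizophrenia, bipolar disorder,
psychiatric comorbidity, Alzheimer's, Lewy body dementia, personality
disorder), mechanisms (getting out of bed, seated to standing, getting to
bed, slipping, tripping, stumbling), psychological and physical reasons
with a medication-side-effect sub-branch (dizziness, muscle weakness,
arrhythmia), and assessment/intervention failure modes. Every minimal cut
set therefore has order 5 with exactly one leaf per branch — the property
the acceptance suite machine-checks.

The reconstruction does **not** claim the full elicited topology (88 risk
factors, 22 OR gates); that model lives in an external open-data deposit,
for which `load_deposited_model` is the adapter seam (native-format
fallback now, schema fingerprint + explicit "adapter required" error for
anything else). Leaf probabilities are an *illustrative overlay*, stored in
a separate data file from the structure so the two are independently
versioned: synthetic values at published-plausible magnitudes for
psychiatric inpatient fall risk, several multi-source entries to exercise
the low/average/high machinery. Every report derived from the fixture
carries the provenance note "reconstruction — illustrative probabilities";
no number computed from it is a claim about the published model's numbers.

## Synthetic-data generator

The generator emulates the statistical shape of elicited patient-safety
trees: a gate skeleton built top-down (guaranteeing reachability), leaves
attached childless-gates-first so every gate keeps ≥ 1 input, AND share set
by `and_fraction` (default 2/24, matching the published model's two
conjunctions among 24 gates), repeats added by wiring a leaf into a second
gate with probability `repeat_rate`, and 1–4 sources per factor with a 30%
expert share. Leaf probabilities default to uniform(0.01, 0.5) — fall-risk
factors are rare-to-moderate events; the extremes 0 and 1 are exercised by
dedicated edge-case fixtures rather than the generator, so generated trees
are never degenerate. What it does not emulate: real elicitation themes'
semantic structure, correlated sources, or probability mass concentrated
on a few dominant factors — so passing the synthetic suite demonstrates
algorithmic correctness, not calibration to any real ward.

## Problem sizes and numerical choices

The verification suite runs 200 random trees with ≤ 12 basic events
against full truth-table enumeration (the oracle is exponential; 12 events
keeps it exact and quick), 60 trees for bound/selector coherence, and 20
trees × 10^6 Monte Carlo draws for simulation consistency (|MC − exact| ≤
4 SE; with 20 fixed seeds the chance of a false alarm is ≈ 0.1%).
Equality tolerances are 1e-12 absolute on probabilities, 1e-6 on the
Birnbaum finite-difference cross-check. Identifier comparison is
case-sensitive exact match throughout.

## Known limitations

- Independence is assumed everywhere; correlated risk factors (e.g. one
  medication causing two side effects) are not representable.
- Exact monotone-DNF probability and cut-set enumeration are worst-case
  exponential; the row cap and truncation expose this honestly instead of
  hiding it.
- The Open-PSA surface is lossy (single point probability per event, no
  themes/provenance); round-trip fidelity is guaranteed only for the
  native JSON/YAML dialect.
- The packaged model's probabilities are illustrative; replicating the
  published headline numbers requires the external deposit and, if its
  schema differs from the native dialect, a bespoke adapter.
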