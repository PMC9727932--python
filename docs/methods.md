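# Methods

This note documents the models, conventions and design choices behind
abagkit, in the order the workflow runs.

## Data model and conventions

Documents are abstract-level: plain text, optional sentence spans, and named
sets of standoff annotations. All offsets are 0-based, half-open, in
character units; an annotation's `text` field must equal the covered
substring, enforced on every read and write. Character case is never
altered anywhere in the toolkit — short antibody clone IDs (`1D05`) are
case-critical tokens.

The BioC dialect is fixed: one passage per document at offset 0, annotation
locations in document coordinates, entity type in an infon keyed `type`,
annotation-set name in an infon keyed `set`, and a passage infon
`annotation_sets` listing set names so that empty sets survive the round
trip. Write∘read is the identity on the data model.

## Lexicon construction and filtering

Raw name tables (surface, type) are deduplicated on the pair; the same
surface may legitimately appear as both Antibody and Antigen, and the
conflict is deferred to the tagger. Compound names of the form
`anti-<AG>-<AB>` contribute their embedded names. Because antigen names
frequently contain hyphens (`IL-6R`, `SARS-CoV-2`) while antibody clone IDs
rarely do, the compound is split at the **last** hyphen after the `anti-`
prefix (matched case-insensitively); the split point is configurable
(`split="first"`).

Filtering removes three classes of misleading entries:

* single-character surfaces (protein-letter abbreviations such as E, G, S);
* pure unsigned-integer surfaces strictly below `min_number`
  (default 1000) — these collide with measurements; `3.5` and `1e3` are not
  pure integers and are kept, a deliberately literal reading;
* surfaces whose lowercase form is a stopword (seeded with
  antigen, antibody, fab, mab, vhh, mg; extensible via a plain-text file).

Filtering is idempotent and only ever removes entries; surfaces are never
rewritten.

## Tokenization and IOB conversion

Tokens are whitespace-delimited segments further split at a fixed character
class — `− ~ / : + ( ) ' ] [ " , _ . > * • #` plus the ASCII hyphen, which
is treated as equivalent to the Unicode minus because PubMed text mixes
both. Separator characters are emitted as their own single-character
tokens (configurable off) so that the token stream exactly tiles the
non-whitespace characters and offsets stay recoverable.

IOB conversion assigns `B-X` to the first token covered by an annotation of
type X and `I-X` to the rest. When an annotation boundary falls strictly
inside a token, the **token is split at the boundary** rather than the
annotation being snapped to token edges: snapping would silently change
the spans being evaluated. CoNLL reading reconstructs a document by
joining tokens with single spaces; an `I-X` with no open entity of type X
is repaired to `B-X` with a warning. The round trip
`to_conll(from_conll(L))` is the identity on token and label columns for
any `L` the converter itself produced (an arbitrary external file whose
tokens contain split characters would be re-split, so only the columns the
converter emits carry the guarantee).

## Dictionary pre-annotation

Every lexicon surface is searched at every position; matches must start and
end on token boundaries (so `HER2` never fires inside `HER2something`).
The case policy defaults to *smart*: surfaces of ≤4 characters match
case-sensitively, longer surfaces case-insensitively — short IDs are
case-critical while long names tolerate synonym case variance; both length
threshold and policy are configurable. Overlapping candidates are resolved
longest-first, then leftmost, so `human ABCC6` beats its embedded `ABCC6`.
When one span matches under both entity types, the default emits a single
annotation flagged `type_conflict` (typed Antibody for determinism) for
human review rather than silently choosing; `prefer_antibody` /
`prefer_antigen` are available. The output is always mutually
non-overlapping, and on bounded corpora is verified in the tests against a
full substring-enumeration oracle.

`diff_annotations` summarizes a manual revision pass against the automatic
output as added / removed / retyped / re-bounded counts per type, pairing
annotations by overlap with same-span pairs preferred.

## Splitting and statistics

Abstracts are grouped by entity presence (both / antibody-only /
antigen-only / none). Splitting is either whole-corpus or group-wise
(stratified within each group); per-set sizes use **largest-remainder
rounding with remainder ties broken toward the training set**, which keeps
every group's composition within one document of the exact ratio and is
fully deterministic given the seed. Groups smaller than 3 yield a warning
and may leave a set empty. "Words per abstract" means tokens from the
corpus tokenizer; unique mentions are distinct covered-text strings per
type, case-sensitive. Averages are carried at full precision and rounded
only in the presentation table (1 decimal).

## Matching, scoring and agreement

All pairing between two annotation sets is one-to-one **maximum** bipartite
matching, computed per document with `scipy.optimize.linear_sum_assignment`.
Greedy pairing would break the guarantee that relaxing the match criterion
never lowers F1; optimal matching makes it provable. Span overlap means ≥1
shared character — a "span-relax" match with a disjoint span would be
meaningless. Inputs are sorted by position first, so ties resolve toward
earliest gold start, then earliest prediction start.

For agreement, admissible pairs carry lexicographic weights
(cardinality ≫ FA ≫ CA ≫ PA ≫ DA, encoded as powers of a base larger than
the set sizes), so the optimum maximizes the number of pairs first, then
full agreements, and so on. Because the total weight determines the
category count vector uniquely (a digit decomposition), the FA/CA/PA/DA/SN
decomposition is exactly symmetric in its two arguments. Multi-annotator
agreement micro-pools pairwise category counts over all annotator pairs
before computing percentages and F1.

Division-by-zero: P, R and F1 are defined as 0 when their denominator is 0;
the empty-vs-empty agreement case is reported as 100% by convention and
flagged `degenerate`. All percentages are carried at full precision and
rounded (2 decimals) only in tables and JSON output.

A note on the reference agreement scores: the strict formula applied to the
two-decimal category components FA=86.54, SN=10.77 yields
86.54/(100 − 5.385)×100 = 91.4654…, which rounds to 91.47; the published
91.46 was evidently computed from unrounded components. The toolkit
reports the value its formula computes.

## Synthetic corpora and perturbations

The generator plants lexicon surfaces into template sentences at recorded
offsets, giving an exact ledger oracle for the tagger, classifier,
statistics and evaluators. Its defaults emulate the target corpus's shape:
group mix (59.6% both, 2.9% antibody-only, 33.1% antigen-only, 4.4% none),
mean mentions per abstract (3.5 AB, 6.5 AG), a 25% within-document surface
repeat rate and a 30% rate of planted confusables (single letters, small
numbers, generic words) that the lexicon filter must remove and the tagger
must ignore. Antibody names are clone-ID-like letter/digit mixes; antigen
names are gene-symbol-like, some with species prefixes or hyphens. What it
does **not** emulate: real biomedical syntax, context-dependent mentions,
nested or discontinuous entities — so green tests demonstrate algorithmic
correctness, not linguistic robustness on real abstracts.

Perturbation operators mirror real annotation error types: deletions
(missed mentions), insertions (spurious mentions over unannotated tokens),
type flips, and span shifts of up to `max_shift` characters. Shifts are
clamped to keep ≥1 character of overlap with the original and to never
collide with another annotation (original spans stay reserved), so each
output's agreement category is known in advance and the perturbation ledger
is an exact oracle for the evaluator. With deletions only at rate d, strict
recall concentrates at 1−d (binomially) and precision is exactly 1; the
test suite checks this on a ~2,100-mention corpus (260 abstracts) within a
3σ band.

## Problem sizes in the tests

The oracle cross-checks run on 500 random documents with ≤8 annotations per
set (exhaustive bitmask-DP search), the tagger oracle on 50 generated
abstracts, the recall-calibration on 260 abstracts; the whole suite
completes in a few seconds on one CPU.

## Known limitations

* The tagger is purely lexical; no context disambiguation, no learning.
* Group-wise split totals depend on the documented rounding rule; other
  reasonable rounding conventions give slightly different set sizes.
* Multi-annotator agreement pooling is pairwise-micro; other aggregation
  conventions exist.
* CoNLL reconstruction normalizes inter-token spacing to single spaces, so
  original character offsets are not preserved across a CoNLL round trip
  (token/label columns are).
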