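# Methods

## The recognition model

`binomen` treats scientific-name recognition as candidate generation
followed by binary classification.

Candidate generation is deliberately high-recall and cheap: a trigram →
bigram → unigram cascade over each sentence, with shape rules (capitalized
genus of at least three letters, or one/two capitals plus a period for an
abbreviated genus; all-lowercase epithets of at least two letters; internal
hyphens allowed; digits never) and a stop-list of common English words that
disqualifies any window containing one. The scan is greedy: at each
position the longest admissible window wins and the scan strides past it,
so emitted candidates never overlap. Precision is delegated entirely to
the classifier; the rules only bound the candidate space.

Both classifiers operate on the same nominal feature vectors. Every
candidate has three token slots; slots beyond the candidate's rank hold an
explicit `<NONE>` sentinel so that all vectors share one key set
(training and prediction then never read a missing key). Contextual
features are the lowercased word and POS tag at 1..cspan positions either
side, `<PAD>` past the sentence edge. POS tags come from a bundled
deterministic rule tagger (closed-class table, suffix rules, default noun)
— its job is to be a stable, self-contained source of coarse context
categories, and any tagger with the same signature can be plugged in.

### Naive Bayes

Conditional tables are additive-smoothed relative frequencies,
P(f=v|c) = (count(v,c)+α)/(count(c)+α(|V_f|+1)), with one reserved cell
for values unseen in training; α defaults to 1 and α=0 falls back to a
fixed 1e-12 floor so logarithms stay finite. Priors are smoothed the same
way. Decisions are pure argmax in log space; an exact tie yields "no"
(the conservative label for a recognizer).

A consequence of the fixed-key design worth knowing: for a uninominal
candidate, the ~32 sentinel-valued slot features are all deterministic
consequences of its rank, but Naive Bayes multiplies their likelihood
ratios independently, so whatever rank imbalance exists between the
positive and negative classes is raised to the ~32nd power. This makes
Naive Bayes noticeably more conservative on single-token names than the
maximum-entropy model, which fits the correlated sentinel weights jointly
and effectively counts that evidence once. Both clear the acceptance bar;
the bundled worked-example model is the MaxEnt one because its
single-token behaviour (e.g. the place-name disambiguation example) is
the more faithful demonstration of context use.

### Maximum entropy

Feature functions are binary indicators over (class, feature-name=value)
pairs observed in training, plus the standard GIS slack function that
tops every (example, class) active-function total up to the constant C.
GIS updates are λₘ += log(E_emp[gₘ]/E_model[gₘ])/C; the training
log-likelihood is recorded per iteration and is non-decreasing (asserted
in tests). Functions with zero empirical count keep weight 0 rather than
diverging to −∞. Training is vectorized over sparse per-class design
matrices. Defaults: 100 iterations, tolerance 1e-6 on the log-likelihood
improvement — GIS's 1/C step means posteriors are still far from the MLE
at that point, but label decisions are already stable; the optional
"gradient" method (L-BFGS on the exact conditional log-likelihood) is
provided where converged posteriors matter. Training is deterministic:
examples are canonically sorted first, and no randomness is involved
anywhere in either estimator.

## Training-set construction

Negatives are *all* token windows of sizes 1–3 of a text assumed to
contain no scientific names — no rule filtering — which teaches the
classifier the shape and contexts of ordinary English, including
capitalized non-names. Positives come from a seed list of verified names
(featurized against an empty context, so context slots are `<PAD>`) and
from bootstrapping: an initial classifier trained on structural features
only (cspan 0) scans an unlabeled corpus, and candidates whose "yes"
posterior reaches the threshold (default 0.99) are added with their real
sentence contexts, together with abbreviated variants (genus replaced by
initial + "."). 

Two choices here deviate from the obvious recipe and deserve a note:

- the *initial* classifier is Naive Bayes by default. At a 0.99 harvest
  threshold the initial model's posterior calibration is what matters, and
  100 GIS iterations leave maximum-entropy posteriors too flat to clear
  such a cut, which starves the bootstrap; Naive Bayes posteriors saturate
  and harvest well. The final classifier is whichever the configuration
  names.
- bootstrapped context positives are replicated up to rough parity with
  the no-context seed positives (duplicates are meaningful frequency
  information to both estimators). Without this, a seed list much larger
  than the harvest leaves the context tables dominated by padding and the
  classifier nearly context-blind.

## The synthetic study

The generator emulates the target prose: English template sentences, a
configurable fraction containing a planted Latin name (60% binomial, 25%
uninominal, 15% trinomial; 15% of name sentences reuse an earlier binomial
in abbreviated form), and the name-free remainder split between plain
filler and capitalized distractors — places and surnames, several with
deliberately Latin-looking endings (Atlanta, Sonora, Patagonia), and
place-context templates ("The city X is in the state of Y") so that
structural features alone cannot separate names from distractors.
Generated names are syllable sequences with Latin endings; stems are
usually consonant-final and sometimes vowel-initial, matching real
genus/epithet morphology (Gymnot-us, Atlant-a). OCR noise applies a small
confusion table (e↔c, l↔i, u↔n, o→e, rn→m, fi→h) per character at a
configurable rate, remapping gold spans and flagging corrupted names.
One `random.Random` seed makes corpus and gold byte-reproducible.

Reference study conditions (all in `binomen.workflows`): 2,000 training
sentences and 500 held-out sentences at name density 0.3 and distractor
rate 0.5; an 800-sentence names-free negative corpus (~21,000 windows, a
realistic multiple of the ~6,000 positives); 5,000 seed names; cspan 1;
bundled stop-list; seed 42. Sub-seeds for the individual corpora are
derived affinely from the master seed.

What passing on this study does and does not show: the generator's
vocabulary is tiny and its sentences templated, so held-out F ≈ 0.95–0.99
demonstrates that the pipeline's machinery (rules, features, estimators,
bootstrap, abbreviation resolution) recovers planted structure, not that
these scores transfer to real books. The qualitative contrasts are the
transferable findings: contextual features raise recall over cspan 0, the
stop-list raises precision, and the classifier recovers OCR-corrupted
names that exact lookup of the clean name list cannot.

## Numerical and design choices

- Character offsets are 0-based half-open; every mention surface re-slices
  its document exactly (asserted everywhere).
- Vowel counts are capped into a "5+" category so they stay nominal for
  both estimators.
- The partitions of {a,e,i,o,u,s,m} default to {vowels}, {s}, {m} and are
  configurable.
- Non-abbreviated uninominal candidates must be ≥ 4 characters (curbs
  single-word noise; configurable).
- Abbreviation resolution matches on the abbreviation's letters against
  the most recent genus in a per-document history fed by full mentions,
  uninominal mentions and previous expansions; expansion is
  annotation-only and never moves a span.
- Models serialize to a versioned JSON file embedding the full feature
  index and the feature-configuration fingerprint; recognition refuses a
  model whose fingerprint differs from the run configuration.
- The stop-list is applied identically at training (bootstrap candidate
  generation) and prediction. Without a stop-list the cascade merges
  English words into candidate windows, which costs recall as well as
  precision — the package asserts only the precision direction of this
  contrast.

## Known limitations

- The rule inventory rejects authorship strings, "sp. nov." markers and
  names with embedded numerals; these are out of scope.
- The tokenizer is Treebank-like, not Treebank-exact (contractions are
  kept whole, hyphenated words are never split).
- Two-letter abbreviations match antecedents case-insensitively past the
  first letter; ambiguous abbreviations always take the most recent
  compatible genus.
- Naive Bayes single-token conservatism (above) is inherent to the fixed
  feature-key design; use the MaxEnt model where uninominal sensitivity
  matters.
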