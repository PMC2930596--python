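"""String similarity between metabolite names.

Chemical synonyms differ in systematic ways — suffix swaps such as
"-ic acid" vs "-ate", Greek-letter spellings, reordered locants — while names
of distinct compounds usually differ in tokens or numbering.  A logistic
regression over symmetric string-pair features separates the two, trained on
within-database synonym sets (all names of one compound are positives;
name pairs of formula-discordant compounds are guaranteed negatives).

The score is a probability of identity in (0, 1).  Pairs at or above the
acceptance threshold (default 0.9) count as "high probability of being
similar"; pairs in [0.5, threshold) are queued for manual review.
"""

from __future__ import annotations

import json
import math
import random
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .model_io import CompoundRecord

DEFAULT_THRESHOLD = 0.9
REVIEW_FLOOR = 0.5

_GREEK = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ω": "omega",
}
# characters allowed to survive normalization (locants need digits, hyphens,
# commas, primes and parentheses)
_KEEP = re.compile(r"[^a-z0-9 ,()'\[\]+-]")
_WS_RUN = re.compile(r"\s+")
_HYPHEN_RUN = re.compile(r"-+")


def normalize_name(name: str) -> str:
    """Lowercase, unify Greek letters, collapse whitespace/hyphen runs."""
    s = name.strip().lower()
    for greek, spelled in _GREEK.items():
        s = s.replace(greek, spelled)
    s = _KEEP.sub("", s)
    s = _WS_RUN.sub(" ", s)
    s = _HYPHEN_RUN.sub("-", s)
    return s.strip(" -")


FEATURE_NAMES = (
    "bigram_dice",
    "prefix_match",
    "suffix_match",
    "number_tokens_agree",
    "acronym_compatible",
    "common_token_count",
    "different_token_count",
)


@dataclass(frozen=True)
class NamePairFeatures:
    """Symmetric feature vector for a pair of normalized names."""

    bigram_dice: float
    prefix_match: float
    suffix_match: float
    number_tokens_agree: bool
    acronym_compatible: bool
    common_token_count: int
    different_token_count: int

    def as_vector(self) -> list[float]:
        return [
            self.bigram_dice,
            self.prefix_match,
            self.suffix_match,
            float(self.number_tokens_agree),
            float(self.acronym_compatible),
            float(self.common_token_count),
            float(self.different_token_count),
        ]


def _bigrams(s: str) -> Counter:
    """Character bigram multiset with start/end boundary markers."""
    padded = "^" + s + "$"
    return Counter(padded[i : i + 2] for i in range(len(padded) - 1))


def bigram_dice(a: str, b: str) -> float:
    """Dice coefficient of boundary-padded character-bigram multisets."""
    ba, bb = _bigrams(a), _bigrams(b)
    inter = sum((ba & bb).values())
    total = sum(ba.values()) + sum(bb.values())
    return 2.0 * inter / total if total else 1.0


def _tokens(s: str) -> list[str]:
    return re.findall(r"[a-z0-9]+", s)


def _acronym(tokens: Sequence[str]) -> str:
    return "".join(t[0] for t in tokens)


def extract_features(a: str, b: str) -> NamePairFeatures:
    """Compute the symmetric feature vector for a pair of raw names."""
    na, nb = normalize_name(a), normalize_name(b)
    if not na or not nb:
        raise ValueError(f"empty name after normalization: {a!r} / {b!r}")
    shorter = min(len(na), len(nb))
    prefix = 0
    while prefix < shorter and na[prefix] == nb[prefix]:
        prefix += 1
    suffix = 0
    while suffix < shorter and na[-1 - suffix] == nb[-1 - suffix]:
        suffix += 1
    nums_a = Counter(re.findall(r"\d+", na))
    nums_b = Counter(re.findall(r"\d+", nb))
    toks_a, toks_b = Counter(_tokens(na)), Counter(_tokens(nb))
    common = sum((toks_a & toks_b).values())
    different = sum((toks_a - toks_b).values()) + sum((toks_b - toks_a).values())
    list_a, list_b = _tokens(na), _tokens(nb)
    acro = (
        _acronym(list_a) == _acronym(list_b)
        or (len(list_a) == 1 and list_a[0] == _acronym(list_b))
        or (len(list_b) == 1 and list_b[0] == _acronym(list_a))
    )
    return NamePairFeatures(
        bigram_dice=bigram_dice(na, nb),
        prefix_match=prefix / shorter,
        suffix_match=suffix / shorter,
        number_tokens_agree=nums_a == nums_b,
        acronym_compatible=acro,
        common_token_count=common,
        different_token_count=different,
    )


@dataclass
class NameModel:
    """Trained logistic scorer: score = logistic(bias + w·features)."""

    weights: dict[str, float]
    bias: float
    threshold: float = DEFAULT_THRESHOLD

    def score(self, a: str, b: str) -> float:
        f = extract_features(a, b)
        z = self.bias + sum(
            w * x for w, x in zip((self.weights[n] for n in FEATURE_NAMES), f.as_vector())
        )
        return 1.0 / (1.0 + math.exp(-z))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "features": list(FEATURE_NAMES),
                    "weights": self.weights,
                    "bias": self.bias,
                    "threshold": self.threshold,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NameModel":
        d = json.loads(Path(path).read_text())
        return cls(weights=d["weights"], bias=d["bias"], threshold=d["threshold"])


def score(model: NameModel, a: str, b: str) -> float:
    return model.score(a, b)


def _formula_discordant(a: CompoundRecord, b: CompoundRecord) -> bool:
    """True when formulas differ in a non-hydrogen element (true non-identity)."""
    fa = {k: v for k, v in a.formula.items() if k != "H"}
    fb = {k: v for k, v in b.formula.items() if k != "H"}
    return bool(fa) and bool(fb) and fa != fb


def build_training_set(
    db: Sequence[CompoundRecord],
    negatives_per_positive: int = 1,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Build labeled name pairs from one database's synonym sets.

    Positives are all unordered synonym pairs within a compound.  Negatives
    are sampled name pairs from distinct compounds whose formulas differ in a
    non-hydrogen element, so the negative label is guaranteed correct; the
    negative count is matched to ``negatives_per_positive`` times the
    positive count.
    """
    positives: list[tuple[str, str, int]] = []
    for c in db:
        names = [n for n in dict.fromkeys(normalize_name(x) for x in c.names) if n]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                positives.append((names[i], names[j], 1))
    if not positives:
        raise ValueError("insufficient training data: no compound with ≥2 synonyms")

    rng = random.Random(seed)
    with_formula = [c for c in db if c.formula and not c.is_generic_class]
    negatives: list[tuple[str, str, int]] = []
    target = negatives_per_positive * len(positives)
    attempts = 0
    while len(negatives) < target and attempts < 200 * target:
        attempts += 1
        ca, cb = rng.sample(with_formula, 2) if len(with_formula) >= 2 else (None, None)
        if ca is None or not _formula_discordant(ca, cb):
            continue
        na = normalize_name(rng.choice(ca.names))
        nb = normalize_name(rng.choice(cb.names))
        if na and nb and na != nb:
            negatives.append((na, nb, 0))
    if not negatives:
        raise ValueError("insufficient training data: no formula-discordant negatives")
    return positives + negatives


def train(
    pairs: Iterable[tuple[str, str, int]],
    l2_strength: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> NameModel:
    """Fit L2-regularized maximum-likelihood logistic weights."""
    import numpy as np
    from sklearn.linear_model import LogisticRegression

    pairs = list(pairs)
    X = np.array([extract_features(a, b).as_vector() for a, b, _ in pairs])
    y = np.array([label for _, _, label in pairs])
    if len(set(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    clf = LogisticRegression(C=1.0 / l2_strength, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    weights = {n: float(w) for n, w in zip(FEATURE_NAMES, clf.coef_[0])}
    return NameModel(weights=weights, bias=float(clf.intercept_[0]), threshold=threshold)


def heuristic_model(threshold: float = DEFAULT_THRESHOLD) -> NameModel:
    """Hand-set prior weights, for databases without usable synonym sets.

    An untrained fallback that rewards high bigram overlap with agreeing
    numeric locants and penalizes extra tokens; use :func:`train` whenever
    within-database synonyms are available.
    """
    return NameModel(
        weights={
            "bigram_dice": 9.0,
            "prefix_match": 1.5,
            "suffix_match": 1.0,
            "number_tokens_agree": 2.0,
            "acronym_compatible": 1.0,
            "common_token_count": 0.5,
            "different_token_count": -1.5,
        },
        bias=-9.0,
        threshold=threshold,
    )


def write_training_tsv(pairs: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name_a\tname_b\tlabel\n")
        for a, b, label in pairs:
            fh.write(f"{a}\t{b}\t{label}\n")
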