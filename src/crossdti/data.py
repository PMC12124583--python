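"""Interaction datasets: CSV I/O, summaries, and synthetic generation.

Interaction records are (SMILES string, protein sequence, binary label)
triples, the record shape of the public DTI benchmarks this model targets.
The reader tolerates comma- and tab-separated files, with or without a
header, and auto-detects column order from content: an all-uppercase
amino-acid field of length >= 10 is the protein, a 0/1 field is the label,
and the remaining field is the drug.

The synthetic generator plants a known rule — a pair interacts exactly when
a fixed drug motif AND a fixed protein motif are both present — into random
sequences with realistic length distributions (log-normal protein lengths,
uniform drug lengths). With zero label noise the planted rule predicts the
labels perfectly, which makes the generator a controlled test bed for the
whole model; it makes no attempt at chemical validity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import PROTEIN_ALPHABET, SMILES_ALPHABET

__all__ = [
    "InteractionRecord",
    "DatasetSummary",
    "SyntheticSpec",
    "LengthFit",
    "read_interactions",
    "write_interactions",
    "summarize",
    "generate_synthetic",
    "length_distribution_fit",
    "celegans_like_interactions",
]

_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass(frozen=True)
class InteractionRecord:
    """One drug-target pair with its binary interaction label."""

    smiles: str
    protein: str
    label: int

    def __post_init__(self):
        if not self.smiles or not self.protein:
            raise ValueError("sequences must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DatasetSummary:
    """Counts and length quantiles for one interaction dataset."""

    n_records: int
    n_positive: int
    n_negative: int
    n_unique_drugs: int
    n_unique_proteins: int
    drug_length_quantiles: dict[float, float]
    protein_length_quantiles: dict[float, float]

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_unique_drugs": self.n_unique_drugs,
            "n_unique_proteins": self.n_unique_proteins,
            "drug_length_quantiles": {str(q): v for q, v in
                                      self.drug_length_quantiles.items()},
            "protein_length_quantiles": {str(q): v for q, v in
                                         self.protein_length_quantiles.items()},
        }


@dataclass
class SyntheticSpec:
    """Parameters of the planted-motif generator.

    A pair is positive iff ``drug_motif`` occurs in the SMILES string and
    ``protein_motif`` occurs in the protein sequence; classes are balanced by
    construction and labels are then flipped independently with probability
    ``label_noise_rate``. ``seed`` fully determines the output.
    """

    n_pairs: int = 1000
    drug_motif: str = "NC1COS"
    protein_motif: str = "HWKDHW"
    label_noise_rate: float = 0.0
    drug_length_range: tuple[int, int] = (20, 80)
    protein_length_median: float = 350.0
    protein_length_sigma: float = 0.45
    protein_length_clip: tuple[int, int] = (50, 1200)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must lie in [0, 0.5)")
        if any(ch not in SMILES_ALPHABET for ch in self.drug_motif):
            raise ValueError("drug_motif must use the SMILES alphabet")
        if any(ch not in PROTEIN_ALPHABET for ch in self.protein_motif):
            raise ValueError("protein_motif must use the amino-acid alphabet")
        if len(self.drug_motif) > self.drug_length_range[0]:
            raise ValueError("drug motif longer than the minimum drug length")
        if len(self.protein_motif) > self.protein_length_clip[0]:
            raise ValueError("protein motif longer than the minimum protein length")


# ---------------------------------------------------------------------------
# reading and writing
# ---------------------------------------------------------------------------

_PROTEIN_RE = re.compile(r"^[A-Z]{10,}$")
_LABELS = {"0": 0, "1": 1, "0.0": 0, "1.0": 1}


def _classify_row(fields: list[str]) -> InteractionRecord | None:
    """Assign (smiles, protein, label) roles to a 3-field row, or None."""
    if len(fields) != 3:
        return None
    fields = [f.strip() for f in fields]
    label_idx = next((i for i, f in enumerate(fields) if f in _LABELS), None)
    if label_idx is None:
        return None
    rest = [i for i in range(3) if i != label_idx]
    prot_idx = next(
        (i for i in rest
         if _PROTEIN_RE.match(fields[i])
         and all(c in PROTEIN_ALPHABET for c in fields[i])),
        None,
    )
    if prot_idx is None:
        # fall back: the longer all-letter field is the protein
        cand = [i for i in rest if _PROTEIN_RE.match(fields[i])]
        if not cand:
            return None
        prot_idx = max(cand, key=lambda i: len(fields[i]))
    drug_idx = next(i for i in rest if i != prot_idx)
    if not fields[drug_idx]:
        return None
    try:
        return InteractionRecord(
            smiles=fields[drug_idx],
            protein=fields[prot_idx],
            label=_LABELS[fields[label_idx]],
        )
    except ValueError:
        return None


def read_interactions(path, dialect: str | None = None) -> list[InteractionRecord]:
    """Parse a comma- or tab-separated interaction file.

    Column order is detected from content, so header-bearing and headerless
    files with any column permutation parse to the same records. Malformed
    rows (wrong field count, non-binary label, empty sequence) are skipped
    with a warning carrying the skip count.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect, None)
    df = pd.read_csv(path, sep=sep, engine="python", header=None, dtype=str,
                     skip_blank_lines=True)
    records: list[InteractionRecord] = []
    skipped = 0
    for row_i, row in enumerate(df.itertuples(index=False)):
        fields = ["" if pd.isna(f) else str(f) for f in row]
        rec = _classify_row(fields)
        if rec is None:
            if row_i == 0:
                continue  # header line
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed row(s) in {path}")
    if not records:
        raise ValueError(f"no parseable interaction rows in {path}")
    return records


def write_interactions(records: list[InteractionRecord], path) -> None:
    """Write records as CSV with a (smiles, protein, label) header; the file
    reads back to exactly the same records."""
    df = pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "protein": [r.protein for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def summarize(records: list[InteractionRecord]) -> DatasetSummary:
    """Exact positive/negative/unique-molecule counts and length quantiles."""
    if not records:
        raise ValueError("cannot summarize an empty dataset")
    labels = np.array([r.label for r in records])
    d_lens = np.array([len(r.smiles) for r in records], dtype=float)
    p_lens = np.array([len(r.protein) for r in records], dtype=float)
    return DatasetSummary(
        n_records=len(records),
        n_positive=int((labels == 1).sum()),
        n_negative=int((labels == 0).sum()),
        n_unique_drugs=len({r.smiles for r in records}),
        n_unique_proteins=len({r.protein for r in records}),
        drug_length_quantiles={q: float(np.quantile(d_lens, q))
                               for q in _QUANTILES},
        protein_length_quantiles={q: float(np.quantile(p_lens, q))
                                  for q in _QUANTILES},
    )


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

def _random_string(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _protein_length(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    lo, hi = spec.protein_length_clip
    val = rng.lognormal(np.log(spec.protein_length_median),
                        spec.protein_length_sigma)
    return int(np.clip(round(val), lo, hi))


def _insert(rng: np.random.Generator, seq: str, motif: str) -> str:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):]


def generate_synthetic(spec: SyntheticSpec) -> list[InteractionRecord]:
    """Sample a balanced planted-motif dataset.

    Positives carry both motifs (inserted at uniform random positions);
    negatives carry at most one (the missing side is rejection-sampled so the
    motif never appears by chance). Labels are then flipped independently
    with probability ``label_noise_rate``, and record order is shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    lo_d, hi_d = spec.drug_length_range

    def sample_drug(with_motif: bool) -> str:
        for _ in range(200):
            s = _random_string(rng, SMILES_ALPHABET,
                               int(rng.integers(lo_d, hi_d + 1)))
            if with_motif:
                return _insert(rng, s, spec.drug_motif)
            if spec.drug_motif not in s:
                return s
        raise RuntimeError("failed to sample a motif-free drug")

    def sample_protein(with_motif: bool) -> str:
        for _ in range(200):
            s = _random_string(rng, PROTEIN_ALPHABET, _protein_length(rng, spec))
            if with_motif:
                return _insert(rng, s, spec.protein_motif)
            if spec.protein_motif not in s:
                return s
        raise RuntimeError("failed to sample a motif-free protein")

    records: list[InteractionRecord] = []
    n_pos = spec.n_pairs // 2
    for i in range(spec.n_pairs):
        positive = i < n_pos
        if positive:
            smiles = sample_drug(True)
            protein = sample_protein(True)
        else:
            mode = rng.integers(0, 3)  # neither / drug only / protein only
            smiles = sample_drug(mode == 1)
            protein = sample_protein(mode == 2)
        label = int(positive)
        if spec.label_noise_rate > 0 and rng.random() < spec.label_noise_rate:
            label = 1 - label
        records.append(InteractionRecord(smiles, protein, label))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def planted_rule_scores(records: list[InteractionRecord],
                        spec: SyntheticSpec) -> np.ndarray:
    """The Bayes-optimal classifier for a planted-motif dataset: 1 when both
    motifs are present, else 0."""
    return np.array(
        [float(spec.drug_motif in r.smiles and spec.protein_motif in r.protein)
         for r in records]
    )


# ---------------------------------------------------------------------------
# length-distribution fitting
# ---------------------------------------------------------------------------

@dataclass
class LengthFit:
    """Empirical protein-length quantiles, a log-normal fit, and the
    recommended truncation length (95th percentile)."""

    quantiles: dict[float, float]
    lognormal_mu: float
    lognormal_sigma: float
    recommended_max_len: int


def length_distribution_fit(records: list[InteractionRecord]) -> LengthFit:
    """Fit the protein-length distribution and recommend a MaxL.

    The log-normal parameters are the mean and population standard deviation
    of log lengths; a zero-variance (constant-length) dataset fits with
    sigma 0 and MaxL equal to that length.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to fit a length distribution")
    lens = np.array([len(r.protein) for r in records], dtype=float)
    logs = np.log(lens)
    mu = float(logs.mean())
    sigma = float(logs.std())
    quantiles = {q: float(np.quantile(lens, q)) for q in _QUANTILES}
    return LengthFit(
        quantiles=quantiles,
        lognormal_mu=mu,
        lognormal_sigma=sigma,
        recommended_max_len=int(np.ceil(quantiles[0.95])),
    )


# ---------------------------------------------------------------------------
# benchmark-shaped stand-in
# ---------------------------------------------------------------------------

def celegans_like_interactions(seed: int = 0) -> list[InteractionRecord]:
    """A synthetic stand-in with the C.elegans benchmark's construction
    counts: 4000 positive (and 4000 negative) interactions over exactly 1434
    unique compounds and 2504 unique proteins.

    The sequences are random strings, not the real benchmark data; only the
    dataset-level counts and rough length statistics are emulated, which is
    what the summary machinery is checked against.
    """
    rng = np.random.default_rng(seed)
    n_drugs, n_proteins, n_pos, n_neg = 1434, 2504, 4000, 4000

    def unique_strings(n, alphabet, lengths):
        out: set[str] = set()
        while len(out) < n:
            out.add(_random_string(rng, alphabet, int(lengths())))
        return sorted(out)[:n]

    drugs = unique_strings(n_drugs, SMILES_ALPHABET,
                           lambda: rng.integers(20, 81))
    proteins = unique_strings(
        n_proteins, PROTEIN_ALPHABET,
        lambda: np.clip(round(rng.lognormal(np.log(350), 0.45)), 50, 1200),
    )
    n_total = n_pos + n_neg
    pairs = []
    for i in range(n_total):
        # the first pass cycles through every protein and drug so each
        # molecule appears at least once
        if i < n_proteins:
            pairs.append((drugs[i % n_drugs], proteins[i]))
        else:
            pairs.append((drugs[rng.integers(n_drugs)],
                          proteins[rng.integers(n_proteins)]))
    labels = np.zeros(n_total, dtype=int)
    labels[rng.choice(n_total, size=n_pos, replace=False)] = 1
    order = rng.permutation(n_total)
    return [InteractionRecord(pairs[i][0], pairs[i][1], int(labels[i]))
            for i in order]
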