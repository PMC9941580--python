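"""Subfamily scoring profiles for kinase-domain classification.

Plant kinases are conventionally classified into groups (RLK-Pelle, CMGC,
CAMK, CK1, STE, TKL, AGC, ...) and subfamilies using profiles built from
curated multi-species domain alignments.  This module represents each
subfamily as a log-odds position-specific score matrix (PSSM) over the
20-letter amino-acid alphabet, scored against every ungapped window of a
query domain sequence.  A classification is accepted when the best profile
score reaches the profile's threshold and beats the runner-up by a margin;
otherwise the sequence falls into the "Unknown" category, the conventional
bucket for sequences that match a kinase domain but no known subfamily.

A profile set is persisted as a directory with a ``manifest.tsv``
(subfamily, group, threshold, margin, matrix file) and one whitespace
matrix file per subfamily.  An adapter is provided to score true HMM files
through pyhmmer when profile HMMs are available instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Match probability used when deriving a PSSM from a consensus sequence.
CONSENSUS_MATCH_P = 0.7
#: Uniform background over the 20 amino acids.
BACKGROUND_P = 1.0 / 20.0

#: Default subfamily catalogue: (subfamily, group).  Groups follow the
#: standard plant-kinome nomenclature; RLK-Pelle is the receptor-like
#: kinase group that dominates plant kinomes.
DEFAULT_CATALOG: tuple[tuple[str, str], ...] = (
    ("RLK-Pelle_DLSV", "RLK-Pelle"),
    ("RLK-Pelle_LRR-XII-1", "RLK-Pelle"),
    ("RLK-Pelle_RLCK-VIIa-2", "RLK-Pelle"),
    ("RLK-Pelle_LysM", "RLK-Pelle"),
    ("CMGC_CDK-PITSLRE", "CMGC"),
    ("CAMK_CDPK", "CAMK"),
    ("CK1_CK1", "CK1"),
    ("STE_STE7", "STE"),
    ("TKL-Pl-4", "TKL"),
    ("AGC_PKA-PKG", "AGC"),
)

#: Internal seed so the default profile set is identical in every session.
_CATALOG_SEED = 902140
DEFAULT_DOMAIN_LENGTH = 180
DEFAULT_SCORE_THRESHOLD = 100.0
DEFAULT_MARGIN = 50.0


@dataclass
class SubfamilyProfile:
    """One subfamily scoring model."""

    subfamily_name: str
    group_name: str
    pssm: np.ndarray  # (L, 20) log-odds
    score_threshold: float
    margin_threshold: float
    consensus: str = ""

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != len(AA_ALPHABET):
            raise ValueError("PSSM must be (L, 20)")

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    def score(self, sequence: str) -> float:
        """Best ungapped-window log-odds score of the profile on ``sequence``.

        Sequences shorter than the profile are scored over the windows of
        the sequence sliding along the profile.
        """
        codes = encode_sequence(sequence)
        L = self.length
        n = codes.size
        if n == 0:
            raise ValueError("empty sequence")
        best = -np.inf
        if n >= L:
            rows = np.arange(L)
            for off in range(n - L + 1):
                s = self.pssm[rows, codes[off:off + L]].sum()
                if s > best:
                    best = s
        else:
            rows = np.arange(n)
            for off in range(L - n + 1):
                s = self.pssm[rows + off, codes].sum()
                if s > best:
                    best = s
        return float(best)


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an amino-acid string as alphabet indices; reject unknown letters."""
    try:
        return np.fromiter(
            (_AA_INDEX[a] for a in sequence), dtype=np.int64, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"illegal amino acid {exc.args[0]!r}") from None


def pssm_from_consensus(consensus: str, match_p: float = CONSENSUS_MATCH_P) -> np.ndarray:
    """Log-odds PSSM giving probability ``match_p`` to the consensus residue."""
    L = len(consensus)
    other_p = (1.0 - match_p) / (len(AA_ALPHABET) - 1)
    pssm = np.full((L, len(AA_ALPHABET)), np.log(other_p / BACKGROUND_P))
    idx = encode_sequence(consensus)
    pssm[np.arange(L), idx] = np.log(match_p / BACKGROUND_P)
    return pssm


class ProfileSet:
    """An ordered collection of subfamily profiles with unique names."""

    def __init__(self, profiles: list[SubfamilyProfile]):
        names = [p.subfamily_name for p in profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subfamily names in profile set")
        self.profiles = list(profiles)
        self._by_name = {p.subfamily_name: p for p in profiles}

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, name: str) -> SubfamilyProfile:
        return self._by_name[name]

    @property
    def subfamilies(self) -> list[str]:
        return [p.subfamily_name for p in self.profiles]

    def group_of(self, subfamily: str) -> str:
        if subfamily == "Unknown":
            return "Unknown"
        return self._by_name[subfamily].group_name

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for p in self.profiles:
            fname = p.subfamily_name.replace("/", "_") + ".pssm"
            header = f"# consensus {p.consensus}\n" if p.consensus else ""
            with open(directory / fname, "w") as fh:
                fh.write(header)
                np.savetxt(fh, p.pssm, fmt="%.6f")
            rows.append(
                (p.subfamily_name, p.group_name, p.score_threshold,
                 p.margin_threshold, fname)
            )
        pd.DataFrame(
            rows, columns=["subfamily", "group", "threshold", "margin", "matrix"]
        ).to_csv(directory / "manifest.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ProfileSet":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        profiles = []
        for row in manifest.itertuples(index=False):
            mat_path = directory / row.matrix
            consensus = ""
            with open(mat_path) as fh:
                first = fh.readline()
                if first.startswith("# consensus"):
                    consensus = first.split()[-1]
            pssm = np.loadtxt(mat_path, comments="#")
            profiles.append(
                SubfamilyProfile(
                    subfamily_name=row.subfamily, group_name=row.group,
                    pssm=pssm, score_threshold=float(row.threshold),
                    margin_threshold=float(row.margin), consensus=consensus,
                )
            )
        return cls(profiles)


def default_profile_set(
    domain_length: int = DEFAULT_DOMAIN_LENGTH,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    margin: float = DEFAULT_MARGIN,
) -> ProfileSet:
    """Build the built-in profile set from a fixed internal seed.

    Each subfamily gets an independent random consensus of ``domain_length``
    residues, so cross-subfamily similarity sits at the ~5% background level
    and the margin rule separates families cleanly.
    """
    rng = np.random.default_rng(_CATALOG_SEED)
    profiles = []
    for name, group in DEFAULT_CATALOG:
        consensus = "".join(rng.choice(list(AA_ALPHABET), size=domain_length))
        profiles.append(
            SubfamilyProfile(
                subfamily_name=name, group_name=group,
                pssm=pssm_from_consensus(consensus),
                score_threshold=score_threshold, margin_threshold=margin,
                consensus=consensus,
            )
        )
    return ProfileSet(profiles)


# --------------------------------------------------------------------------
# pyhmmer adapter
# --------------------------------------------------------------------------

def score_with_hmms(hmm_path: str | Path, sequences: dict[str, str]):
    """Score protein sequences against profile HMMs in ``hmm_path``.

    Returns ``{seq_id: (best_hmm_name, bit_score)}`` for sequences with at
    least one hit.  This is the adapter used when true subfamily HMMs are
    available in place of the built-in PSSMs.
    """
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    digital = [
        pyhmmer.easel.TextSequence(name=name.encode(), sequence=seq).digitize(alphabet)
        for name, seq in sequences.items()
    ]
    def _text(value) -> str:
        return value.decode() if isinstance(value, bytes) else str(value)

    best: dict[str, tuple[str, float]] = {}
    with pyhmmer.plan7.HMMFile(str(hmm_path)) as hmms:
        for hits in pyhmmer.hmmsearch(hmms, digital):
            query = _text(hits.query.name)
            for hit in hits:
                name = _text(hit.name)
                if name not in best or hit.score > best[name][1]:
                    best[name] = (query, float(hit.score))
    return best
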