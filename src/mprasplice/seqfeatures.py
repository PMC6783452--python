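"""Per-variant sequence and structure features for splicing prediction.

Features mirror the regulatory inputs known to shape splice-site choice:
regional hexamer counts, cumulative RNA-binding-protein PWM log-odds scores,
splice-site strength, GC content (absolute and intron-relative) and RNA
secondary structure (minimum free energy and per-position pairedness).

Feature extraction is a pure function of sequence plus a region scheme; no
hidden state is carried between calls.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._dna import BASES, encode

Window = Tuple[int, int]

#: ordered region names per splicing type (regions tile the variable region)
REGION_NAMES = {
    "retained_intron": ("exon_up", "intron", "exon_down"),
    "cassette_exon": ("intron_up", "exon", "intron_down"),
    "tandem5": ("exon", "alt_exon", "intron"),
    "tandem3": ("intron", "alt_exon", "exon"),
}

ALL_HEXAMERS = ["".join(h) for h in itertools.product(BASES, repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}


@dataclass
class RegionScheme:
    """Named, non-overlapping regions covering a designed variable region."""

    splicing_type: str
    regions: List[Tuple[str, Window]]

    def __post_init__(self) -> None:
        last = None
        for name, (a, b) in self.regions:
            if a >= b:
                raise ValueError(f"region {name} is empty or inverted")
            if last is not None and a < last:
                raise ValueError("regions must be ordered and non-overlapping")
            last = b

    @classmethod
    def from_anchors(
        cls, splicing_type: str, length: int, anchors: Sequence[int]
    ) -> "RegionScheme":
        """Derive the canonical three-region scheme from splice-site anchors."""
        if len(anchors) != 2:
            raise ValueError("expected two splice-site anchors")
        names = REGION_NAMES[splicing_type]
        a1, a2 = anchors
        bounds = [(0, a1), (a1, a2), (a2, length)]
        return cls(splicing_type, list(zip(names, bounds)))


def count_hexamers(sequence: str, regions: Mapping[str, Window]) -> Dict[str, np.ndarray]:
    """Count overlapping occurrences of all 4096 hexamers per region.

    Returns a region -> length-4096 uint32 vector map indexed like
    :data:`ALL_HEXAMERS`. A region shorter than 6 nt yields all zeros; a
    region of length L yields a total of L - 5 counts.
    """
    out = {}
    for name, (a, b) in regions.items():
        sub = sequence[a:b]
        counts = np.zeros(4096, dtype=np.uint32)
        if len(sub) >= 6:
            enc = encode(sub).astype(np.int64)
            idx = np.zeros(len(enc) - 5, dtype=np.int64)
            for j in range(6):
                idx = idx * 4 + enc[j : j + len(enc) - 5]
            counts = np.bincount(idx, minlength=4096).astype(np.uint32)
        out[name] = counts
    return out


# --- PWM scoring -------------------------------------------------------------


@dataclass
class MotifPWM:
    """A position-probability matrix with a background distribution."""

    motif_id: str
    rbp_name: str
    matrix: np.ndarray  # positions x 4 (ACGT), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be positions x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.matrix) - np.log(self.background)

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str, p: float = 0.7) -> "MotifPWM":
        """Build a PWM concentrating probability ``p`` on the consensus base."""
        m = np.full((len(consensus), 4), (1 - p) / 3)
        for i, b in enumerate(consensus):
            m[i, BASES.index(b)] = p
        return cls(motif_id, motif_id, m)


def read_attract_pwms(path: str) -> List[MotifPWM]:
    """Read PWMs in the ATtRACT text layout: a ``>matrix_id<TAB>name`` header
    line followed by one whitespace-separated row of 4 probabilities per
    motif position."""
    pwms: List[MotifPWM] = []
    header: Optional[Tuple[str, str]] = None
    rows: List[List[float]] = []

    def flush() -> None:
        if header is not None:
            pwms.append(MotifPWM(header[0], header[1], np.array(rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def score_rbp_motifs(
    sequence: str,
    regions: Mapping[str, Window],
    pwms: Sequence[MotifPWM],
) -> Dict[Tuple[str, str], float]:
    """Cumulative log-odds of every PWM in every region.

    The score is the sum, over all alignment positions of the motif within
    the region, of the per-position log-odds of the aligned bases — a
    binding-site occupancy proxy. Regions shorter than the motif score 0.
    """
    out = {}
    enc_regions = {name: encode(sequence[a:b]) for name, (a, b) in regions.items()}
    for pwm in pwms:
        lo = pwm.log_odds
        m = len(pwm)
        for name, enc in enc_regions.items():
            n = len(enc) - m + 1
            if n <= 0:
                out[(name, pwm.motif_id)] = 0.0
                continue
            total = 0.0
            for j in range(m):
                total += lo[j, enc[j : j + n]].sum()
            out[(name, pwm.motif_id)] = float(total)
    return out


# --- splice-site strength ----------------------------------------------------

DONOR_CONSENSUS = "CAGGTAAGT"  # 3 exonic + 6 intronic
ACCEPTOR_CONSENSUS_23 = "TTTTT" + "CTCCTTTCCTTTCAG" + "GTC"  # 20 intronic + 3 exonic

#: windows around the anchor in the shared signed-coordinate convention
SITE_WINDOWS = {"donor": (-3, 6), "acceptor": (-20, 3)}


class PWMScorer:
    """First-order log-odds scorer for donor (9-mer) / acceptor (23-mer)
    windows, built from consensus-weighted probability matrices."""

    def __init__(self, p: float = 0.7):
        self.pwms = {
            "donor": MotifPWM.from_consensus("donor", DONOR_CONSENSUS, p),
            "acceptor": MotifPWM.from_consensus("acceptor", ACCEPTOR_CONSENSUS_23, p),
        }

    def __call__(self, window_seq: str, site_kind: str) -> float:
        pwm = self.pwms[site_kind]
        if len(window_seq) != len(pwm):
            raise ValueError(
                f"{site_kind} window must be {len(pwm)} nt, got {len(window_seq)}"
            )
        lo = pwm.log_odds
        enc = encode(window_seq)
        return float(lo[np.arange(len(enc)), enc].sum())


class TableScorer:
    """Scorer backed by an externally supplied k-mer score table (e.g.
    precomputed maximum-entropy model scores), read from a two-column TSV
    of ``kmer<TAB>score``."""

    def __init__(self, donor_path: Optional[str] = None, acceptor_path: Optional[str] = None):
        self.tables: Dict[str, Dict[str, float]] = {}
        for kind, path in (("donor", donor_path), ("acceptor", acceptor_path)):
            if path is not None:
                tab = {}
                with open(path) as fh:
                    for line in fh:
                        if not line.strip():
                            continue
                        kmer, score = line.split()[:2]
                        tab[kmer.upper()] = float(score)
                self.tables[kind] = tab

    def __call__(self, window_seq: str, site_kind: str) -> float:
        return self.tables[site_kind][window_seq.upper()]


def splice_site_strength(
    sequence: str,
    anchor: int,
    site_kind: str,
    scorer: Optional[Callable[[str, str], float]] = None,
) -> float:
    """Score the strength of a donor (9-mer window, -3:+6) or acceptor
    (23-mer window, -20:+3) splice site with a pluggable scorer."""
    if site_kind not in SITE_WINDOWS:
        raise ValueError("site_kind must be 'donor' or 'acceptor'")
    a, b = SITE_WINDOWS[site_kind]
    lo, hi = anchor + a, anchor + b
    if not (0 <= lo < hi <= len(sequence)):
        raise ValueError(f"{site_kind} window at anchor {anchor} outside sequence")
    scorer = scorer or PWMScorer()
    return scorer(sequence[lo:hi], site_kind)


# --- GC features -------------------------------------------------------------


def gc_features(
    sequence: str, regions: Mapping[str, Window], relative_mode: str = "difference"
) -> Dict[str, float]:
    """GC content per region plus relative intronic GC (intron GC normalized
    to the flanking exonic regions, as a difference by default or a ratio)."""
    out = {}
    for name, (a, b) in regions.items():
        sub = sequence[a:b]
        out[f"gc_{name}"] = (sub.count("G") + sub.count("C")) / len(sub)
    intron_keys = [k for k in out if "intron" in k]
    exon_keys = [k for k in out if "exon" in k]
    if intron_keys and exon_keys:
        gc_intron = float(np.mean([out[k] for k in intron_keys]))
        gc_exon = float(np.mean([out[k] for k in exon_keys]))
        if relative_mode == "difference":
            out["relative_intronic_gc"] = gc_intron - gc_exon
        elif relative_mode == "ratio":
            out["relative_intronic_gc"] = gc_intron / gc_exon if gc_exon else math.nan
        else:
            raise ValueError(f"unknown relative_mode {relative_mode!r}")
    return out


# --- secondary structure -----------------------------------------------------


def _nussinov_structure(seq: str, min_loop: int = 3) -> str:
    """Base-pair-maximization fallback folder (approximate; no thermodynamics).

    Returns a dot-bracket string for the pairing that maximizes the number of
    Watson-Crick/GU pairs with a minimum hairpin loop of ``min_loop``.
    """
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    n = len(seq)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in pairs:
                    cand = dp[i, k - 1] if k > i else 0
                    best = max(best, cand + dp[k + 1, j - 1] + 1)
            dp[i, j] = best
    struct = ["."] * n

    def traceback(i: int, j: int) -> None:
        if i >= j:
            return
        if dp[i, j] == dp[i, j - 1]:
            traceback(i, j - 1)
            return
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in pairs:
                cand = (dp[i, k - 1] if k > i else 0) + dp[k + 1, j - 1] + 1
                if dp[i, j] == cand:
                    struct[k], struct[j] = "(", ")"
                    traceback(i, k - 1)
                    traceback(k + 1, j - 1)
                    return
        traceback(i, j - 1)  # pragma: no cover

    traceback(0, n - 1)
    return "".join(struct)


def _fold(seq: str, engine: str) -> Tuple[str, float]:
    rna = seq.replace("T", "U")
    if engine in ("auto", "vienna"):
        try:
            import RNA  # ViennaRNA python bindings

            return RNA.fold(rna)
        except ImportError:
            if engine == "vienna":
                raise
    struct = _nussinov_structure(seq)
    return struct, 0.0 if "(" not in struct else -float(struct.count("("))


def structure_features(
    sequence: str,
    windows: Mapping[str, Window],
    engine: str = "auto",
    pairedness: str = "binary",
) -> Dict[str, object]:
    """Fold each window and report its minimum free energy (kcal/mol) and a
    per-position pairedness vector derived from the predicted structure.

    ``engine`` selects the folder: ``vienna`` (thermodynamic), ``nussinov``
    (approximate base-pair maximization; energies are pair counts, not
    kcal/mol) or ``auto`` (vienna when importable, else the fallback).
    """
    if pairedness not in ("binary",):
        raise ValueError("only binary pairedness from the MFE structure is supported")
    out: Dict[str, object] = {}
    for name, (a, b) in windows.items():
        if not (0 <= a < b <= len(sequence)):
            raise ValueError(f"window {name} outside sequence")
        sub = sequence[a:b]
        struct, mfe = _fold(sub, engine)
        out[f"mfe_{name}"] = float(mfe)
        out[f"paired_{name}"] = np.array([0.0 if c == "." else 1.0 for c in struct])
    return out


# --- feature-matrix assembly -------------------------------------------------


def build_feature_matrix(
    sequences: Mapping[str, str],
    schemes: Mapping[str, RegionScheme],
    anchors: Mapping[str, Sequence[int]],
    pwms: Sequence[MotifPWM] = (),
    include_hexamers: bool = False,
    structure_windows: Optional[Mapping[str, Window]] = None,
    scorer: Optional[Callable[[str, str], float]] = None,
) -> pd.DataFrame:
    """Assemble a per-variant feature table (GC, splice-site strengths,
    optional PWM scores / hexamer counts / structure MFEs) indexed by
    variant id."""
    rows = {}
    for vid, seq in sequences.items():
        scheme = schemes[vid]
        regions = dict(scheme.regions)
        feats: Dict[str, float] = {}
        feats.update(gc_features(seq, regions))
        site_kinds = (
            ("donor", "acceptor")
            if scheme.splicing_type in ("retained_intron", "cassette_exon")
            else (("donor", "donor") if scheme.splicing_type == "tandem5" else ("acceptor", "acceptor"))
        )
        for pos, kind, label in zip(anchors[vid], site_kinds, ("site1", "site2")):
            try:
                feats[f"strength_{label}"] = splice_site_strength(seq, pos, kind, scorer)
            except ValueError:
                feats[f"strength_{label}"] = np.nan
        if pwms:
            for (region, motif), score in score_rbp_motifs(seq, regions, pwms).items():
                feats[f"rbp_{region}_{motif}"] = score
        if include_hexamers:
            for region, counts in count_hexamers(seq, regions).items():
                nz = np.nonzero(counts)[0]
                for i in nz:
                    feats[f"hexamer_{region}_{ALL_HEXAMERS[i]}"] = float(counts[i])
        if structure_windows:
            sf = structure_features(seq, structure_windows)
            for k, v in sf.items():
                if k.startswith("mfe_"):
                    feats[k] = float(v)
        rows[vid] = feats
    df = pd.DataFrame.from_dict(rows, orient="index")
    if include_hexamers:
        hex_cols = [c for c in df.columns if c.startswith("hexamer_")]
        df[hex_cols] = df[hex_cols].fillna(0.0)
    df.index.name = "variant_id"
    return df
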