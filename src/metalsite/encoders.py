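"""Window encodings: AA one-hot, BLOSUM62, PAM250 and PSSM profiles.

Every encoding maps a window of ``2*w + 1`` residues to ``(2*w + 1) * 20``
reals (260 at the default flank of 6), one 20-vector per window position
in PSI-BLAST amino-acid column order (A R N D C Q E G H I L K M F P S T
W Y V).  Padding positions contribute an exact all-zero row under every
encoding.  PSSM log-odds are squashed into (0, 1) with the logistic
function; substitution-matrix rows are min-max rescaled to [0, 1] over
the whole matrix so all encodings share a common range.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy.special import expit

from .io import AMINO_ACIDS, PAD, ProteinRecord, ResidueSite, Window, windows_for_sites

ENCODINGS = ("AA", "BLOSUM62", "PAM250", "PSSM")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class PssmParseError(ValueError):
    """Raised when a PSI-BLAST ASCII matrix cannot be parsed."""


@dataclass
class PssmProfile:
    """Per-position log-odds profile of one protein.

    ``scores`` has one row per sequence position and 20 columns in
    PSI-BLAST order; ``residues`` (when present) is the query residue
    column of the file, used to cross-check against the sequence.
    """

    protein_id: str
    scores: np.ndarray
    residues: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"profile must be (L, 20), got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile contains non-finite values")

    def validate_against(self, record: ProteinRecord) -> None:
        """Check row count and residue letters against a record."""
        if self.scores.shape[0] != len(record.sequence):
            raise ValueError(
                f"{self.protein_id}: profile has {self.scores.shape[0]} rows, "
                f"sequence has {len(record.sequence)}"
            )
        if self.residues is not None:
            for i, (a, b) in enumerate(zip(self.residues, record.sequence), start=1):
                # X in either column means an unknown/cleaned letter; skip those.
                if PAD not in (a, b) and a != b:
                    raise ValueError(
                        f"{self.protein_id}: profile residue {a} != sequence "
                        f"residue {b} at position {i}"
                    )


def parse_psiblast_pssm(path: str | Path, protein_id: str | None = None) -> PssmProfile:
    """Parse the ASCII matrix written by PSI-BLAST ``-out_ascii_pssm``.

    Only the first 20 numeric columns per row (the log-odds block) are
    kept; the trailing weighted-percentage block and footer statistics
    are ignored.  Truncated rows and non-numeric cells raise
    :class:`PssmParseError` with the offending line number.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if header is None:
                if len(toks) >= 20 and all(
                    len(t) == 1 and t in AMINO_ACIDS for t in toks[:20]
                ):
                    header = toks[:20]
                continue
            if not toks:
                if rows:
                    break
                continue
            if not toks[0].lstrip("-").isdigit():
                break  # footer (Lambda/K statistics)
            if len(toks) < 22:
                raise PssmParseError(
                    f"{path}:{lineno}: row has {len(toks) - 2} score columns, need 20"
                )
            residues.append(toks[1])
            try:
                vals = [float(t) for t in toks[2:22]]
            except ValueError as exc:
                raise PssmParseError(
                    f"{path}:{lineno}: non-numeric score cell"
                ) from exc
            rows.append(vals)
    if header is None or not rows:
        raise PssmParseError(f"{path}: no PSSM table found")
    scores = np.asarray(rows, dtype=float)
    if header != list(AMINO_ACIDS):
        order = [header.index(aa) for aa in AMINO_ACIDS]
        scores = scores[:, order]
    return PssmProfile(
        protein_id=protein_id or path.stem,
        scores=scores,
        residues="".join(residues),
    )


def scale_pssm_value(x):
    """Squash a raw log-odds score into (0, 1) with the logistic function.

    Strictly increasing, so the ordering of raw scores is preserved at
    every window position.  Accepts scalars or arrays.
    """
    return expit(x)


@lru_cache(maxsize=None)
def _scaled_substitution_matrix(name: str) -> np.ndarray:
    """20x20 substitution matrix in canonical order, min-max scaled to [0, 1]."""
    mat = substitution_matrices.load(name)
    sub = np.array(
        [[float(mat[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
    )
    lo, hi = sub.min(), sub.max()
    return (sub - lo) / (hi - lo)


def encode_window(
    window: Window,
    encoding: str,
    profile: PssmProfile | None = None,
) -> np.ndarray:
    """Encode one window into a length ``(2*w + 1) * 20`` vector.

    AA: one-hot row per residue.  BLOSUM62 / PAM250: the scaled
    substitution-matrix row of the residue.  PSSM: the logistic-scaled
    profile row of the corresponding sequence position (``profile``
    required).  Padding positions are all-zero rows in every encoding.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; choose from {ENCODINGS}")
    if encoding == "PSSM" and profile is None:
        raise ValueError("PSSM encoding requires a profile")
    w = window.w
    rows = np.zeros((2 * w + 1, 20))
    for k, off in enumerate(range(-w, w + 1)):
        aa = window.context[k]
        if aa == PAD:
            continue
        if encoding == "AA":
            rows[k, AA_INDEX[aa]] = 1.0
        elif encoding in ("BLOSUM62", "PAM250"):
            rows[k] = _scaled_substitution_matrix(encoding)[AA_INDEX[aa]]
        else:  # PSSM
            idx = window.site.position - 1 + off
            if not 0 <= idx < profile.scores.shape[0]:
                raise ValueError(
                    f"profile for {window.site.protein_id} too short for "
                    f"position {window.site.position} offset {off}"
                )
            rows[k] = scale_pssm_value(profile.scores[idx])
    return rows.ravel()


def encode_dataset(
    sites: list[ResidueSite],
    records: list[ProteinRecord] | dict[str, ProteinRecord],
    encoding: str,
    profiles: dict[str, PssmProfile] | None = None,
    saap_features=None,
    w: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a list of sites into a feature table and 0/1 label vector.

    Row order equals site order; labels are 1 for binding sites.  When
    ``saap_features`` (a ranked list from the SAAP miner) is given, each
    row is extended by the corresponding binary pair indicators.
    """
    if not sites:
        extra = len(saap_features) if saap_features else 0
        return np.zeros((0, (2 * w + 1) * 20 + extra)), np.zeros(0, dtype=int)
    windows = windows_for_sites(sites, records, w)
    vectors = []
    for win in windows:
        prof = None
        if encoding == "PSSM":
            if profiles is None or win.site.protein_id not in profiles:
                raise ValueError(
                    f"no PSSM profile for {win.site.protein_id} "
                    f"(site at position {win.site.position})"
                )
            prof = profiles[win.site.protein_id]
        vectors.append(encode_window(win, encoding, prof))
    X = np.asarray(vectors)
    if saap_features:
        from .saap import indicator_matrix

        X = np.hstack([X, indicator_matrix(windows, saap_features)])
    y = np.array([1 if s.is_binding else 0 for s in sites], dtype=int)
    return X, y


def write_feature_table(
    path: str | Path,
    X: np.ndarray,
    y: np.ndarray,
    sites: list[ResidueSite],
    w: int = 6,
) -> None:
    """Export an encoded dataset as a headered TSV for inspection."""
    n_base = (2 * w + 1) * 20
    cols = [
        f"{off:+d}{aa}"
        for off in range(-w, w + 1)
        for aa in AMINO_ACIDS
    ][: n_base]
    cols += [f"saap_{i + 1}" for i in range(X.shape[1] - n_base)]
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\t" + "\t".join(cols) + "\n")
        for site, row, label in zip(sites, X, y):
            vals = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{site.protein_id}\t{site.position}\t{label}\t{vals}\n")
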