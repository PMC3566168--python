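"""Model/Results facade over the full prediction pipeline.

:class:`MetalSiteModel` bundles a dataset (records, optional profiles)
with the method's configuration; :meth:`MetalSiteModel.fit` runs SAAP
mining, forward selection and cross-validated evaluation, trains the
final network on all sites, and returns a :class:`MetalSiteResults`
carrying the pooled confusion counts, the metric suite, the selection
audit trail and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline, rbfn, saap
from .encoders import PssmProfile, parse_psiblast_pssm
from .io import (
    DEFAULT_FLANK,
    ProteinRecord,
    ResidueSite,
    extract_sites,
    read_annotations,
    read_fasta,
    windows_for_sites,
)


class MetalSiteModel:
    """Metal-binding site predictor for one center residue type.

    Parameters
    ----------
    records : list of ProteinRecord
        Annotated proteins (training data).
    center_residue : "C" or "H"
        Which candidate residue type this model discriminates; separate
        models are fitted for cysteine and histidine.
    encoding : one of AA, BLOSUM62, PAM250, PSSM
        Window encoding; PSSM requires ``profiles``.
    profiles : dict mapping protein id -> PssmProfile, optional
    use_saaps : bool
        Whether to mine and forward-select pair indicator features.
    max_saap_features : int, optional
        Cap on the forward-selection prefix scan length.
    """

    def __init__(
        self,
        records: list[ProteinRecord],
        center_residue: str = "C",
        encoding: str = "PSSM",
        profiles: dict[str, PssmProfile] | None = None,
        *,
        w: int = DEFAULT_FLANK,
        sigma: float = rbfn.DEFAULT_BANDWIDTH,
        ridge: float = rbfn.DEFAULT_RIDGE,
        alpha: float = 0.05,
        use_saaps: bool = True,
        max_saap_features: int | None = None,
    ) -> None:
        if center_residue not in ("C", "H"):
            raise ValueError("center_residue must be C or H")
        self.records = {r.id: r for r in records}
        self.center_residue = center_residue
        self.encoding = encoding
        self.profiles = profiles
        self.w = w
        self.sigma = sigma
        self.ridge = ridge
        self.alpha = alpha
        self.use_saaps = use_saaps
        self.max_saap_features = max_saap_features
        self.sites: list[ResidueSite] = [
            s
            for r in records
            for s in extract_sites(r)
            if s.residue == center_residue
        ]

    @classmethod
    def from_files(
        cls,
        fasta: str | Path,
        annotations: str | Path,
        pssm_dir: str | Path | None = None,
        **kwargs,
    ) -> "MetalSiteModel":
        """Build a model from a FASTA file, annotation TSV and PSSM directory."""
        records, _ = read_fasta(fasta)
        records, _ = read_annotations(annotations, records)
        profiles = None
        if pssm_dir is not None:
            profiles = load_profiles(pssm_dir, records)
        return cls(records, profiles=profiles, **kwargs)

    def fit(
        self, cv_folds: int = 10, seed: int = 0, leak_free: bool = True
    ) -> "MetalSiteResults":
        """Mine, select, train and cross-validate.

        SAAPs are mined and ranked on the full training dataset and
        scanned by forward selection.  With ``leak_free`` (default) the
        reported CV confusion counts come from a run that re-mines
        SAAPs inside each training split and keeps its top k* pairs, so
        no test fold influences feature definitions; with
        ``leak_free=False`` the globally selected list is reused in
        every fold (the classical, leaky protocol).
        """
        plan = pipeline.make_cv_plan(self.sites, k=cv_folds, seed=seed)
        selection = None
        saap_config = None
        if self.use_saaps:
            windows = windows_for_sites(self.sites, self.records, self.w)
            catalog = saap.mine_saaps(windows, self.alpha)
            selection = pipeline.forward_select_saaps(
                self.sites,
                self.records,
                catalog,
                plan,
                encoding=self.encoding,
                profiles=self.profiles,
                sigma=self.sigma,
                ridge=self.ridge,
                w=self.w,
                max_features=self.max_saap_features,
            )
            if leak_free:
                saap_config = pipeline.SaapConfig(
                    mode="per_fold", alpha=self.alpha, n_features=selection.k_star
                )
            else:
                saap_config = pipeline.SaapConfig(
                    mode="fixed", features=selection.features
                )
        cv = pipeline.run_cv(
            self.sites,
            self.records,
            plan,
            encoding=self.encoding,
            profiles=self.profiles,
            saap_config=saap_config,
            sigma=self.sigma,
            ridge=self.ridge,
            w=self.w,
        )
        final = pipeline.train_model(
            self.sites,
            self.records,
            encoding=self.encoding,
            profiles=self.profiles,
            saap_features=selection.features if selection else None,
            sigma=self.sigma,
            ridge=self.ridge,
            w=self.w,
        )
        return MetalSiteResults(model=self, network=final, cv=cv, selection=selection)


@dataclass
class MetalSiteResults:
    """Fit outcome: final network, CV evaluation and selection audit."""

    model: MetalSiteModel
    network: rbfn.RbfnModel
    cv: pipeline.CvResult
    selection: pipeline.SelectionResult | None = None
    metrics: pipeline.MetricsReport = field(init=False)

    def __post_init__(self) -> None:
        self.metrics = pipeline.compute_metrics(self.cv.counts)

    @property
    def counts(self) -> pipeline.ConfusionCounts:
        return self.cv.counts

    @property
    def selected_saaps(self) -> list[saap.SaapFeature]:
        return self.selection.features if self.selection else []

    def predict(
        self,
        records: list[ProteinRecord],
        profiles: dict[str, PssmProfile] | None = None,
    ) -> pd.DataFrame:
        """Per-site decision values and labels for new proteins."""
        sites = [
            s
            for r in records
            for s in extract_sites(r)
            if s.residue == self.model.center_residue
        ]
        if not sites:
            return pd.DataFrame(
                columns=[
                    "protein_id",
                    "position",
                    "residue",
                    "g_binding",
                    "g_non_binding",
                    "prediction",
                ]
            )
        G, pred = pipeline.predict_sites(self.network, sites, records, profiles)
        return pd.DataFrame(
            {
                "protein_id": [s.protein_id for s in sites],
                "position": [s.position for s in sites],
                "residue": [s.residue for s in sites],
                "g_binding": G[:, 0],
                "g_non_binding": G[:, 1],
                "prediction": np.where(pred == 1, "binding", "non-binding"),
            }
        )

    def evaluate_independent(
        self,
        records: list[ProteinRecord],
        profiles: dict[str, PssmProfile] | None = None,
    ) -> tuple[pipeline.ConfusionCounts, pipeline.MetricsReport]:
        """Independent-test evaluation on held-out annotated proteins."""
        sites = [
            s
            for r in records
            for s in extract_sites(r)
            if s.residue == self.model.center_residue
        ]
        return pipeline.run_independent_test(self.network, sites, records, profiles)

    def summary(self) -> str:
        """Human-readable fit summary in the standard report layout."""
        m = self.model
        c = self.cv.counts
        row = pipeline.format_report_row(c, self.metrics)
        lines = [
            "Metal-binding site prediction — fit summary",
            "=" * 60,
            f"Center residue:      {m.center_residue}",
            f"Encoding:            {m.encoding} (window {2 * m.w + 1})",
            f"Sites:               {len(m.sites)} "
            f"({c.tp + c.fn} binding / {c.tn + c.fp} non-binding)",
            f"RBFN:                sigma={m.sigma}, ridge={m.ridge}, "
            f"centers={self.network.centers.shape[0]}",
        ]
        if self.selection is not None:
            sel = ", ".join(str(f) for f in self.selected_saaps[:5])
            more = (
                f" (+{len(self.selected_saaps) - 5} more)"
                if len(self.selected_saaps) > 5
                else ""
            )
            lines += [
                f"SAAPs selected:      k* = {self.selection.k_star}"
                + (f": {sel}{more}" if sel else ""),
                f"Base CV accuracy:    {100 * self.selection.base_accuracy:.1f}%",
            ]
        lines += [
            "-" * 60,
            f"{self.cv.plan.k}-fold CV (seed {self.cv.plan.seed}), pooled:",
            "  " + "  ".join(f"{k}={row[k]}" for k in ("TP", "FP", "TN", "FN")),
            "  "
            + "  ".join(
                f"{k}={row[k]}"
                for k in ("Sensitivity", "Precision", "Specificity", "Accuracy", "MCC")
            ),
            "=" * 60,
        ]
        return "\n".join(lines)


def load_profiles(
    pssm_dir: str | Path, records: list[ProteinRecord]
) -> dict[str, PssmProfile]:
    """Load ``<id>.pssm`` files for records and validate them."""
    pssm_dir = Path(pssm_dir)
    profiles = {}
    for rec in records:
        path = pssm_dir / f"{rec.id}.pssm"
        if not path.exists():
            raise FileNotFoundError(f"no PSSM file for {rec.id}: {path}")
        prof = parse_psiblast_pssm(path, rec.id)
        prof.validate_against(rec)
        profiles[rec.id] = prof
    return profiles
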