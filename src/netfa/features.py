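"""Subjects x tracts fractional-anisotropy feature tables.

Each column is one white-matter tract, identified as ``network::tract`` so
that tracts stay grouped into their named brain networks (affective, face
perception, mentalizing, mirroring in the study design).  Values are mean
FA per tract, nominally in [0, 1]; NaN marks a missing measurement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["TractFeatureMatrix", "qc_filter_tracts"]

_SEP = "::"
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class TractFeatureMatrix:
    """Immutable-ish wrapper around a subjects x tracts FA DataFrame.

    Column names must be ``network::tract`` and unique; the subject index
    must be unique.  ``network_of`` maps each tract column to its network.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated subject ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated tract ids: {dups}")
        for col in values.columns:
            if _SEP not in str(col):
                raise ValueError(
                    f"tract column {col!r} is not of the form 'network{_SEP}tract'"
                )
        self.values = values.astype(float)
        self.values.index.name = "subject_id"

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def tract_ids(self) -> list:
        return list(self.values.columns)

    @property
    def network_of(self) -> dict:
        return {t: str(t).split(_SEP, 1)[0] for t in self.values.columns}

    @property
    def networks(self) -> list:
        seen = []
        for t in self.values.columns:
            net = str(t).split(_SEP, 1)[0]
            if net not in seen:
                seen.append(net)
        return seen

    @property
    def shape(self):
        return self.values.shape

    def network(self, name: str) -> pd.DataFrame:
        """The sub-matrix of tracts belonging to one named network."""
        cols = [t for t in self.values.columns if str(t).split(_SEP, 1)[0] == name]
        if not cols:
            raise KeyError(f"no tracts recorded for network {name!r}; "
                           f"networks present: {self.networks}")
        return self.values[cols]

    def subset_subjects(self, subjects) -> "TractFeatureMatrix":
        return TractFeatureMatrix(self.values.loc[list(subjects)])

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path, header_lines=()):
        """Write as TSV (tab-separated, 'NA' for missing, full precision)."""
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path) -> "TractFeatureMatrix":
        """Read a feature table written by :meth:`to_tsv`.

        Malformed numeric entries are reported with their row and column
        location; non-rectangular tables and duplicate ids raise.
        """
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                          na_values=["NA"], keep_default_na=False)
        if "subject_id" not in raw.columns:
            raise ValueError(f"{path}: missing 'subject_id' column")
        raw = raw.set_index("subject_id")
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"{path}: malformed numeric value {raw.iat[r, c]!r} at "
                f"subject {raw.index[r]!r}, tract {raw.columns[c]!r}"
            )
        return cls(numeric)


def qc_filter_tracts(features: TractFeatureMatrix,
                     max_missing_fraction: float = 0.5):
    """Drop tracts with too many missing-or-zero FA entries.

    Mirrors the tract-level exclusion applied at tractography time (a tract
    is dropped when tracing failed for more than half of the subjects):
    here a tract column is excluded when strictly more than
    ``max_missing_fraction`` of subjects have a missing or zero FA value.
    Entries at exactly the threshold are retained.

    Returns ``(filtered_matrix, report)`` where ``report`` is a DataFrame
    with one row per excluded tract (tract, network, n_bad, fraction_bad).
    Raises ``ValueError`` if every tract of some network would be excluded.
    """
    vals = features.values
    n = len(vals)
    bad = vals.isna() | (vals == 0)
    frac = bad.sum(axis=0) / n
    drop = frac[frac > max_missing_fraction].index.tolist()
    report = pd.DataFrame({
        "tract": drop,
        "network": [features.network_of[t] for t in drop],
        "n_bad": [int(bad[t].sum()) for t in drop],
        "fraction_bad": [float(frac[t]) for t in drop],
    })
    kept = [t for t in vals.columns if t not in set(drop)]
    kept_networks = {str(t).split(_SEP, 1)[0] for t in kept}
    lost = [net for net in features.networks if net not in kept_networks]
    if lost:
        raise ValueError(f"QC excluded every tract of network(s) {lost}")
    if drop:
        warnings.warn(f"QC excluded {len(drop)} tract(s): {drop}", stacklevel=2)
    return TractFeatureMatrix(vals[kept]), report
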