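"""Cohort-level stability study: the modelling front-end of the package.

:class:`StabilityStudy` is built from a tidy feature table (one row per
patient / ROI / dose volume / feature) and its :meth:`~StabilityStudy.fit`
returns a :class:`StabilityResults` carrying

* the cohort-average CV per (feature, ROI, fraction group) with its
  four-way category,
* the stability ICC(A,1) per (feature, ROI, fraction group) over the
  patients x aligned-replicates table, with F-test p-values,
* the signed percent difference vs the error-free feature value, averaged
  over patients with zero-baseline patients excluded and tallied,
* the fraction-consistency ICC per (feature, ROI) across the fraction-group
  means,
* CV category counts per (ROI, fraction group) that, together with the
  invalid/undefined tallies, always partition the 93 features.

The tidy table uses the columns ``patient, roi, fraction_group, replicate,
feature_class, feature_name, value, valid`` where ``fraction_group`` is an
integer number of fractions or the string ``"original"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stability as st
from .dosiomics import CANONICAL_ORDER, N_FEATURES

REQUIRED_COLUMNS = (
    "patient", "roi", "fraction_group", "replicate",
    "feature_class", "feature_name", "value", "valid",
)

ICC_SIGNIFICANCE_LEVEL = 0.01
PD_HIGHLIGHT_PERCENT = 50.0
ICC_BINS = (0.5, 0.75, 0.9)
FRACTION_CONSISTENCY_THRESHOLD = 0.95


class StabilityStudy:
    """Stability model for a cohort feature table.

    Parameters
    ----------
    features:
        Tidy DataFrame with the columns listed in :data:`REQUIRED_COLUMNS`.
    """

    def __init__(self, features: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        self.features = features.copy()
        self.features["fraction_group"] = self.features["fraction_group"].astype(str)
        groups = sorted(
            int(g) for g in self.features["fraction_group"].unique() if g != "original"
        )
        if not groups:
            raise ValueError("feature table contains no error-dose groups")
        if "original" not in set(self.features["fraction_group"]):
            raise ValueError("feature table contains no error-free baseline rows")
        self.fraction_groups = groups
        self.rois = sorted(self.features["roi"].unique())
        self.patients = sorted(self.features["patient"].unique())
        self._check_complete()

    @classmethod
    def from_features_csv(cls, path: str) -> "StabilityStudy":
        return cls(pd.read_csv(path))

    def _check_complete(self) -> None:
        """Every (patient, roi, group, replicate) cell must carry all features."""
        err = self.features[self.features["fraction_group"] != "original"]
        counts = err.groupby(
            ["patient", "roi", "fraction_group", "replicate"], sort=False
        ).size()
        bad = counts[counts != N_FEATURES]
        if len(bad):
            raise ValueError(
                f"incomplete feature table: {len(bad)} (patient, roi, group, "
                f"replicate) cells do not have {N_FEATURES} features; first "
                f"offenders: {bad.index[:5].tolist()}"
            )
        n_rep = err.groupby(["roi", "fraction_group"])["replicate"].nunique()
        if n_rep.nunique() != 1:
            raise ValueError("unequal replicate counts across fraction groups")

    # ------------------------------------------------------------------ fit

    def fit(self) -> "StabilityResults":
        feats = self.features
        err = feats[feats["fraction_group"] != "original"].copy()
        err["fraction_group"] = err["fraction_group"].astype(int)
        ori = feats[feats["fraction_group"] == "original"]

        key = ["roi", "feature_class", "feature_name"]
        invalid = (
            feats.groupby(key)["valid"].all().rename("all_valid").reset_index()
        )

        # --- per-patient CV, then cohort average -------------------------
        per_pat = (
            err.groupby(["roi", "fraction_group", "feature_class",
                         "feature_name", "patient"])["value"]
            .apply(lambda v: st.coefficient_of_variation(v.to_numpy()))
            .rename("cv_percent")
            .reset_index()
        )
        gkey = ["roi", "fraction_group", "feature_class", "feature_name"]
        cv = (
            per_pat.groupby(gkey)["cv_percent"]
            .agg(cv_percent="mean",
                 n_undefined=lambda v: int(v.isna().sum()))
            .reset_index()
        )
        cv = cv.merge(invalid, on=key)
        defined = cv["all_valid"] & cv["cv_percent"].notna()
        cv["cv_category"] = [
            st.categorize_cv(c) if d else "undefined"
            for c, d in zip(cv["cv_percent"], defined)
        ]

        # --- stability ICC over patients x aligned replicates ------------
        icc_rows = []
        for (roi, grp, fcls, fname), sub in err.groupby(gkey):
            ok = bool(invalid.set_index(key)["all_valid"].loc[(roi, fcls, fname)])
            if not ok:
                icc_rows.append((roi, grp, fcls, fname, np.nan, np.nan, False))
                continue
            tab = sub.pivot_table(
                index="patient", columns="replicate", values="value"
            ).to_numpy()
            icc, p = st.icc_absolute_agreement(tab)
            icc_rows.append(
                (roi, grp, fcls, fname, icc, p,
                 bool(np.isfinite(p) and p < ICC_SIGNIFICANCE_LEVEL))
            )
        icc_df = pd.DataFrame(
            icc_rows, columns=gkey + ["icc", "icc_p", "significant"]
        )

        # --- percent difference vs the error-free baseline ---------------
        ori_map = ori.set_index(["patient", "roi", "feature_class",
                                 "feature_name"])["value"]
        pd_pat = []
        for (roi, grp, fcls, fname, pat), sub in err.groupby(gkey + ["patient"]):
            f0 = ori_map.loc[(pat, roi, fcls, fname)]
            pd_pat.append((roi, grp, fcls, fname, pat,
                           st.percent_difference(f0, sub["value"].to_numpy())))
        pd_pat = pd.DataFrame(
            pd_pat, columns=gkey + ["patient", "pd_percent"]
        )
        pd_df = (
            pd_pat.groupby(gkey)["pd_percent"]
            .agg(pd_percent="mean",
                 n_excluded=lambda v: int(v.isna().sum()))
            .reset_index()
        )
        pd_df = pd_df.merge(invalid, on=key)
        pd_df["large_pd"] = pd_df["all_valid"] & (
            pd_df["pd_percent"].abs() > PD_HIGHLIGHT_PERCENT
        )

        # --- fraction-consistency ICC across group means ------------------
        rep_means = (
            err.groupby(key + ["fraction_group", "patient"])["value"]
            .mean()
            .reset_index()
        )
        fc_rows = []
        for (roi, fcls, fname), sub in rep_means.groupby(key):
            ok = bool(invalid.set_index(key)["all_valid"].loc[(roi, fcls, fname)])
            if not ok:
                fc_rows.append((roi, fcls, fname, np.nan, np.nan, False))
                continue
            tab = sub.pivot_table(
                index="patient", columns="fraction_group", values="value"
            ).to_numpy()
            icc, p = st.icc_absolute_agreement(tab)
            fc_rows.append((roi, fcls, fname, icc, p,
                            bool(np.isfinite(icc)
                                 and icc < FRACTION_CONSISTENCY_THRESHOLD)))
        fc_df = pd.DataFrame(
            fc_rows,
            columns=key + ["icc", "icc_p", "below_threshold"],
        )

        # --- CV category counts per (roi, group) --------------------------
        counts = (
            cv.groupby(["roi", "fraction_group", "cv_category"])
            .size()
            .unstack(fill_value=0)
        )
        for cat in st.CV_CATEGORIES + ("undefined",):
            if cat not in counts.columns:
                counts[cat] = 0
        counts = counts[list(st.CV_CATEGORIES) + ["undefined"]].reset_index()

        return StabilityResults(
            study=self,
            cv_table=cv.drop(columns="all_valid"),
            per_patient_cv=per_pat,
            icc_table=icc_df,
            pd_table=pd_df.drop(columns="all_valid"),
            fraction_consistency=fc_df,
            cv_category_counts=counts,
        )


@dataclass
class StabilityResults:
    """Fitted stability tables for one cohort (see :class:`StabilityStudy`)."""

    study: StabilityStudy
    cv_table: pd.DataFrame
    per_patient_cv: pd.DataFrame
    icc_table: pd.DataFrame
    pd_table: pd.DataFrame
    fraction_consistency: pd.DataFrame
    cv_category_counts: pd.DataFrame

    def unstable_features(self, threshold: float = 0.9) -> pd.DataFrame:
        """Features whose stability ICC falls below ``threshold``, binned.

        Bins follow the reliability guideline cut points 0.5 / 0.75 / 0.9.
        """
        sub = self.icc_table[self.icc_table["icc"] < threshold].copy()
        bins = [-np.inf, *ICC_BINS]
        labels = ["ICC < 0.5", "0.5 <= ICC < 0.75", "0.75 <= ICC < 0.9"]
        sub["icc_bin"] = pd.cut(sub["icc"], bins=bins + [np.inf],
                                labels=labels + ["stable"], right=False)
        return sub[sub["icc_bin"] != "stable"]

    def summary(self) -> str:
        lines = []
        n_pat = len(self.study.patients)
        groups = self.study.fraction_groups
        lines.append("Dosiomic feature stability under interfractional error")
        lines.append("=" * 56)
        lines.append(
            f"patients: {n_pat}   fraction groups: {groups}   "
            f"features: {N_FEATURES}   ROIs: {self.study.rois}"
        )
        lines.append("")
        lines.append("CV category counts (features per ROI x fraction group):")
        lines.append(self.cv_category_counts.to_string(index=False))
        lines.append("")
        unstable = self.unstable_features()
        lines.append(
            f"features with stability ICC < 0.9: {len(unstable)} "
            f"(of {len(self.icc_table)} feature/ROI/group cells)"
        )
        if len(unstable):
            lines.append(
                unstable[["roi", "fraction_group", "feature_class",
                          "feature_name", "icc", "icc_bin"]].to_string(index=False)
            )
        lines.append("")
        big_pd = self.pd_table[self.pd_table["large_pd"]]
        lines.append(
            f"features with |mean PD| > {PD_HIGHLIGHT_PERCENT:.0f}%: {len(big_pd)}"
        )
        fc_low = self.fraction_consistency[self.fraction_consistency["below_threshold"]]
        lines.append(
            "fraction-consistency ICC < "
            f"{FRACTION_CONSISTENCY_THRESHOLD}: {len(fc_low)} feature/ROI cells"
        )
        return "\n".join(lines)

    def save_tables(self, outdir: str) -> dict[str, str]:
        """Write the report CSVs; returns {table name: path}."""
        os.makedirs(outdir, exist_ok=True)
        tables = {
            "cv_table": self.cv_table,
            "icc_table": self.icc_table,
            "pd_table": self.pd_table,
            "cv_category_counts": self.cv_category_counts,
            "fraction_consistency_icc": self.fraction_consistency,
        }
        paths = {}
        for name, df in tables.items():
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False)
            paths[name] = path
        return paths

    def plot_cv_categories(self, path: str | None = None):
        """Bar panels of CV category counts, one panel per ROI."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rois = self.study.rois
        fig, axes = plt.subplots(2, 2, figsize=(9, 7), squeeze=False)
        cats = list(st.CV_CATEGORIES)
        for ax, roi in zip(axes.ravel(), rois):
            sub = self.cv_category_counts[self.cv_category_counts["roi"] == roi]
            x = np.arange(len(sub))
            bottom = np.zeros(len(sub))
            for cat in cats:
                ax.bar(x, sub[cat].to_numpy(), bottom=bottom, label=cat)
                bottom += sub[cat].to_numpy()
            ax.set_xticks(x)
            ax.set_xticklabels(sub["fraction_group"].tolist())
            ax.set_title(roi)
            ax.set_xlabel("fractions")
            ax.set_ylabel("features")
        axes[0, 0].legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
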