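"""Cohort- and breed-level summaries of the inbreeding metrics.

All operations are deterministic transformations of their inputs; the
TSV outputs are designed so downstream modelling (e.g. a general linear
model of metric-by-breed differences) can be done in any stats package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["breed_summary", "metric_correlations", "local_inbreeding_profile",
           "segment_age_distribution"]

OVERALL = "OVERALL"


def breed_summary(values: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Descriptive statistics per breed and metric.

    ``values`` must carry a ``breed`` column plus one column per metric;
    quantiles use linear interpolation (numpy default, type 7).  An
    ``OVERALL`` row pools every individual.
    """
    if "breed" not in values.columns:
        raise ValueError("values must have a 'breed' column")
    metrics = metrics or [c for c in values.columns
                          if c not in ("breed", "individual")]
    rows = []
    groups = [(b, g) for b, g in values.groupby("breed", sort=True)]
    groups.append((OVERALL, values))
    for breed, g in groups:
        for metric in metrics:
            x = g[metric].to_numpy(dtype=float)
            if x.size == 0:
                raise ValueError(f"no individuals for breed {breed!r}")
            rows.append({
                "breed": breed, "metric": metric, "n": x.size,
                "min": x.min(), "q1": np.quantile(x, 0.25),
                "median": np.quantile(x, 0.5), "mean": x.mean(),
                "sd": x.std(ddof=1) if x.size > 1 else np.nan,
                "q3": np.quantile(x, 0.75), "max": x.max(),
            })
    return pd.DataFrame(rows)


def metric_correlations(values: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Pairwise Pearson correlations between inbreeding metrics.

    Zero-variance metrics yield NaN entries (flagged, not an error).
    Requires at least 3 individuals.
    """
    metrics = metrics or [c for c in values.columns
                          if c not in ("breed", "individual")]
    if len(values) < 3:
        raise ValueError("need at least 3 individuals for correlations")
    return values[metrics].corr(method="pearson")


def local_inbreeding_profile(posteriors, labels):
    """Mean total-HBD probability per marker per breed, with a per-class
    decomposition.

    ``posteriors`` maps individual id to a markers x (K+1) posterior
    matrix (non-HBD last); all individuals must share one marker map.
    Returns ``(total, per_class)``: a markers x breeds DataFrame and a
    dict breed -> markers x (K+1) mean posterior.
    """
    by_breed: dict = {}
    for iid, gamma in posteriors.items():
        by_breed.setdefault(labels[iid], []).append(np.asarray(gamma))
    total = {}
    per_class = {}
    for breed, gammas in sorted(by_breed.items()):
        mean = np.mean(gammas, axis=0)
        per_class[breed] = mean
        total[breed] = 1.0 - mean[:, -1]
    return pd.DataFrame(total), per_class


def segment_age_distribution(segments_or_counts, labels,
                             n_hbd_classes: int = 11) -> pd.DataFrame:
    """Per-breed proportion of HBD segments in each age class.

    Accepts either class-annotated ROH segments or a mapping individual
    -> expected per-class segment counts (e.g. EM expected class draws).
    Proportions are over the HBD classes only and sum to 1 for every
    breed with at least one segment; breeds without segments get NaN.
    """
    counts: dict = {}
    if isinstance(segments_or_counts, dict):
        for iid, vec in segments_or_counts.items():
            vec = np.asarray(vec, dtype=float)[:n_hbd_classes]
            breed = labels[iid]
            counts[breed] = counts.get(breed, 0) + vec
    else:
        for seg in segments_or_counts:
            if seg.class_index >= n_hbd_classes:
                continue
            breed = labels[seg.individual]
            vec = counts.setdefault(breed, np.zeros(n_hbd_classes))
            vec[seg.class_index] += 1
    breeds = sorted(set(labels.values()))
    out = pd.DataFrame(np.nan, index=breeds,
                       columns=[f"class{k}" for k in range(n_hbd_classes)])
    for breed in breeds:
        vec = counts.get(breed)
        if vec is not None and np.sum(vec) > 0:
            out.loc[breed] = np.asarray(vec, float) / np.sum(vec)
    return out
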