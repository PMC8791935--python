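"""Stringency Index (SI) construction from OxCGRT-style policy indicators.

The SI summarises nine government-response indicators — the eight
containment-and-closure policies C1–C8 and the public-information campaign
H1 — each recorded daily as an ordinal level between 0 (no measure) and an
indicator-specific maximum.  Every indicator is standardised to [0, 1] by
dividing by its maximum, the nine standardised values are averaged so each
policy contributes equally, and the mean is rescaled to [0, 100].

For the per-policy analysis a *leave-one-out* SI is used: the same mean over
the remaining eight indicators, with the studied policy entered separately
as a standardised regressor.
"""

from __future__ import annotations

import pandas as pd

#: The nine SI component indicators with their ordinal maxima (OxCGRT scale).
SI_INDICATORS: dict[str, int] = {
    "C1": 3,  # school closing
    "C2": 3,  # workplace closing
    "C3": 2,  # cancel public events
    "C4": 4,  # restrictions on gatherings
    "C5": 2,  # close public transport
    "C6": 3,  # stay-at-home requirements
    "C7": 2,  # restrictions on internal movement
    "C8": 4,  # international travel controls
    "H1": 2,  # public information campaigns
}

PANEL_COLUMNS = ["city_id", "date", "indicator_id", "level", "max_level"]


class PolicyPanelError(ValueError):
    """Raised when a policy panel violates its contract."""


def standardize_indicator(level: int, max_level: int) -> float:
    """Standardise an ordinal policy level to the unit interval (level / max)."""
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if level < 0 or level > max_level:
        raise ValueError(f"level {level} outside [0, {max_level}]")
    return level / max_level


def validate_policy_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format policy panel and return it with parsed dates.

    Requires columns (city_id, date, indicator_id, level, max_level), all
    nine SI indicators for every (city, date), no duplicates, and
    0 <= level <= max_level.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise PolicyPanelError(f"policy panel missing columns: {missing}")
    if len(panel) == 0:
        raise PolicyPanelError("policy panel is empty")
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"])
    bad = out[~out["indicator_id"].isin(SI_INDICATORS)]
    if len(bad):
        raise PolicyPanelError(
            f"unknown indicator ids: {sorted(bad['indicator_id'].unique())}"
        )
    over = out[(out["level"] < 0) | (out["level"] > out["max_level"])]
    if len(over):
        rows = (over.index[:5] + 1).tolist()
        raise PolicyPanelError(f"level outside [0, max_level] at rows {rows}")
    dup = out.duplicated(subset=["city_id", "date", "indicator_id"])
    if dup.any():
        rows = (out.index[dup][:5] + 1).tolist()
        raise PolicyPanelError(f"duplicate (city, date, indicator) rows at {rows}")
    counts = out.groupby(["city_id", "date"])["indicator_id"].nunique()
    gaps = counts[counts != len(SI_INDICATORS)]
    if len(gaps):
        city, date = gaps.index[0]
        raise PolicyPanelError(
            f"not all 9 indicators present for city {city!r} on {date.date()}"
        )
    return out


def _standardized(panel: pd.DataFrame) -> pd.DataFrame:
    out = panel.copy()
    out["z"] = out["level"] / out["max_level"]
    return out


def compute_si(panel: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Stringency Index per (city, date): 100 x mean of the 9 standardised levels.

    Returns a frame with columns (city_id, date, si), si in [0, 100].
    """
    if validate:
        panel = validate_policy_panel(panel)
    z = _standardized(panel)
    si = z.groupby(["city_id", "date"], as_index=False)["z"].mean()
    si["si"] = 100.0 * si.pop("z")
    return si


def si_without(panel: pd.DataFrame, excluded: str, validate: bool = True) -> pd.DataFrame:
    """Leave-one-out SI: 100 x mean of the 8 remaining standardised indicators."""
    if excluded not in SI_INDICATORS:
        raise ValueError(f"{excluded!r} is not an SI component ({sorted(SI_INDICATORS)})")
    if validate:
        panel = validate_policy_panel(panel)
    z = _standardized(panel[panel["indicator_id"] != excluded])
    si = z.groupby(["city_id", "date"], as_index=False)["z"].mean()
    si["si"] = 100.0 * si.pop("z")
    return si


def standardize_policy_variable(
    panel: pd.DataFrame, indicator_id: str, validate: bool = True
) -> pd.DataFrame:
    """Per city-day standardised level of one policy: 0 when off, 1 at maximum.

    Returns a frame with columns (city_id, date, z).
    """
    if indicator_id not in SI_INDICATORS:
        raise ValueError(f"{indicator_id!r} is not an SI component")
    if validate:
        panel = validate_policy_panel(panel)
    sub = panel[panel["indicator_id"] == indicator_id]
    out = _standardized(sub)[["city_id", "date", "z"]].reset_index(drop=True)
    return out


def read_policy_panel(path) -> pd.DataFrame:
    """Read and validate a policies.csv file (long format, ISO-8601 dates)."""
    try:
        panel = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise PolicyPanelError(f"empty policy file: {path}") from err
    return validate_policy_panel(panel)


def write_policy_panel(panel: pd.DataFrame, path) -> None:
    """Write a policy panel in the policies.csv dialect (ISO-8601 dates)."""
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[PANEL_COLUMNS].to_csv(path, index=False)
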