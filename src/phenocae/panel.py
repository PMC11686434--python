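"""Spectra panels: loading, normalization, and genotype grouping.

A *panel* is the universal input of the pipeline: one row per plot/plant,
three metadata columns (``genotype``, ``environment``, ``replicate``),
optional ``trait:<name>`` columns, and one numeric-headered column per
wavelength (nm).  All reflectance values of a panel share a single global
min/max pair when normalized, so the dataset extremes map to exactly 0
and 1.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenocae")

META_COLUMNS = ("genotype", "environment", "replicate")
TRAIT_PREFIX = "trait:"


class PanelError(ValueError):
    """Schema, parse or integrity failure while handling a panel."""


def _is_float(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


@dataclasses.dataclass
class SpectraPanel:
    """Reflectance spectra plus plot metadata.

    Attributes
    ----------
    meta : pandas.DataFrame
        Columns ``genotype``, ``environment``, ``replicate`` (strings),
        one row per sample, aligned with ``values``.
    wavelengths : numpy.ndarray
        Strictly increasing wavelength grid in nm.
    values : numpy.ndarray
        Reflectance matrix ``[n_samples, n_wavelengths]``.
    traits : pandas.DataFrame or None
        Optional per-sample trait values (one column per trait).
    normalized : bool
        Whether dataset-level min-max normalization has been applied.
    norm_constants : tuple(float, float) or None
        ``(min_dataset, max_dataset)`` used for normalization.
    """

    meta: pd.DataFrame
    wavelengths: np.ndarray
    values: np.ndarray
    traits: pd.DataFrame | None = None
    normalized: bool = False
    norm_constants: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PanelError("values must be a 2-D matrix")
        if self.values.shape[1] != self.wavelengths.size:
            raise PanelError(
                f"values has {self.values.shape[1]} columns but grid has "
                f"{self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise PanelError("wavelength grid must be strictly increasing")
        if len(self.meta) != self.values.shape[0]:
            raise PanelError("metadata and values row counts differ")
        if not np.all(np.isfinite(self.values)):
            raise PanelError("panel contains non-finite reflectance values")
        keys = list(zip(self.meta["genotype"], self.meta["environment"], self.meta["replicate"]))
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys)[pd.Series(keys).duplicated()].iloc[0]
            raise PanelError(f"duplicate (genotype, environment, replicate) key: {dup}")
        if self.normalized:
            if self.norm_constants is None:
                raise PanelError("normalized panel must carry norm_constants")
            if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
                raise PanelError("normalized panel has values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def sample_keys(self) -> list[tuple[str, str, str]]:
        return list(zip(self.meta["genotype"], self.meta["environment"], self.meta["replicate"]))


@dataclasses.dataclass(frozen=True)
class GenotypeGroup:
    """The E*N plots of one genotype, in environment-major order.

    ``members[k]`` is a row index into the panel; member ``k`` belongs to
    environment ``k // N`` — all replicates of environment 1 first, then
    environment 2, and so on.
    """

    genotype_id: str
    members: tuple[int, ...]
    E: int
    N: int

    def __post_init__(self) -> None:
        if len(self.members) != self.E * self.N:
            raise PanelError(
                f"group {self.genotype_id}: {len(self.members)} members, expected {self.E * self.N}"
            )

    @property
    def P(self) -> int:
        return self.E * self.N

    def environment_of(self, k: int) -> int:
        """0-based environment index of member ``k``."""
        return k // self.N


# ---------------------------------------------------------------------------
# CSV I/O


def load_panel(path: str | Path) -> SpectraPanel:
    """Read a panel CSV (metadata + numeric wavelength columns).

    Raises :class:`PanelError` naming the offending column/row on schema,
    parse or integrity failures.
    """
    path = Path(path)
    if not path.exists():
        raise PanelError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise PanelError(f"{path}: panel has a header but no rows")
    for col in META_COLUMNS:
        if col not in df.columns:
            raise PanelError(f"{path}: missing metadata column '{col}'")
    trait_cols = [c for c in df.columns if c.startswith(TRAIT_PREFIX)]
    wl_cols: list[str] = []
    wls: list[float] = []
    for c in df.columns:
        if c in META_COLUMNS or c in trait_cols:
            continue
        try:
            wls.append(float(c))
        except ValueError as exc:
            raise PanelError(f"{path}: column '{c}' is neither metadata nor a numeric wavelength") from exc
        wl_cols.append(c)
    if len(wl_cols) < 2:
        raise PanelError(f"{path}: need at least 2 wavelength columns, found {len(wl_cols)}")
    order = np.argsort(wls)  # header order is verified, not silently fixed
    if not np.array_equal(order, np.arange(len(wls))):
        raise PanelError(f"{path}: wavelength columns are not in increasing order")

    values = np.empty((len(df), len(wl_cols)))
    for j, c in enumerate(wl_cols):
        raw = df[c]
        if raw.isna().any():
            row = int(np.flatnonzero(raw.isna())[0])
            raise PanelError(f"{path}: missing value at row {row}, column '{c}'")
        try:
            # numpy's strtod round-trips float64 exactly; pandas' fast
            # to_numeric parser does not
            values[:, j] = raw.to_numpy(dtype=str).astype(np.float64)
        except ValueError as exc:
            bad = next(v for v in raw if not _is_float(v))
            row = int(np.flatnonzero(raw == bad)[0])
            raise PanelError(
                f"{path}: non-numeric value {bad!r} at row {row}, column '{c}'"
            ) from exc

    meta = df[list(META_COLUMNS)].astype(str).reset_index(drop=True)
    traits = None
    if trait_cols:
        traits = pd.DataFrame(
            {
                c[len(TRAIT_PREFIX):]: [
                    np.float64(v) if isinstance(v, str) and _is_float(v) else np.nan
                    for v in df[c]
                ]
                for c in trait_cols
            }
        )
    return SpectraPanel(meta=meta, wavelengths=np.array(wls), values=values, traits=traits)


def write_panel(panel: SpectraPanel, path: str | Path) -> None:
    """Write a panel to CSV; :func:`load_panel` round-trips it bit-identically."""
    df = panel.meta.copy()
    if panel.traits is not None:
        for name in panel.traits.columns:
            df[f"{TRAIT_PREFIX}{name}"] = panel.traits[name].to_numpy()
    wl_headers = [np.format_float_positional(w, trim="-") for w in panel.wavelengths]
    spec_df = pd.DataFrame(panel.values, columns=wl_headers)
    pd.concat([df, spec_df], axis=1).to_csv(path, index=False)


def load_traits(path: str | Path) -> pd.DataFrame:
    """Read a standalone trait table keyed by (genotype, environment, replicate)."""
    df = pd.read_csv(path, dtype={c: str for c in META_COLUMNS})
    for col in META_COLUMNS:
        if col not in df.columns:
            raise PanelError(f"{path}: trait table missing key column '{col}'")
    return df


def attach_traits(panel: SpectraPanel, trait_table: pd.DataFrame) -> SpectraPanel:
    """Join a standalone trait table onto a panel by the sample key.

    Trait columns are every non-key column; samples missing from the table
    get NaN trait values.
    """
    merged = panel.meta.merge(trait_table, on=list(META_COLUMNS), how="left")
    trait_cols = [c for c in trait_table.columns if c not in META_COLUMNS]
    if not trait_cols:
        raise PanelError("trait table has no trait columns")
    traits = merged[trait_cols].astype(float).reset_index(drop=True)
    if panel.traits is not None:
        traits = pd.concat([panel.traits.reset_index(drop=True), traits], axis=1)
    return SpectraPanel(
        meta=panel.meta,
        wavelengths=panel.wavelengths,
        values=panel.values,
        traits=traits,
        normalized=panel.normalized,
        norm_constants=panel.norm_constants,
    )


# ---------------------------------------------------------------------------
# Normalization (dataset-level min-max)


def minmax_normalize(panel: SpectraPanel) -> SpectraPanel:
    """Scale every value by the panel-wide extremes: x -> (x - min) / (max - min).

    A single (min, max) pair is taken over *all* values of the panel, so the
    global minimum maps to exactly 0 and the global maximum to exactly 1.
    The constants are stored on the returned panel for later inversion and
    for applying identical scaling at inference time.
    """
    if panel.normalized:
        raise PanelError("panel is already normalized")
    lo = float(panel.values.min())
    hi = float(panel.values.max())
    if hi <= lo:
        raise PanelError(f"degenerate normalization: dataset min == max == {lo}")
    values = (panel.values - lo) / (hi - lo)
    return SpectraPanel(
        meta=panel.meta,
        wavelengths=panel.wavelengths,
        values=values,
        traits=panel.traits,
        normalized=True,
        norm_constants=(lo, hi),
    )


def denormalize(panel: SpectraPanel) -> SpectraPanel:
    """Invert :func:`minmax_normalize` using the stored constants."""
    if not panel.normalized or panel.norm_constants is None:
        raise PanelError("panel is not normalized")
    lo, hi = panel.norm_constants
    return SpectraPanel(
        meta=panel.meta,
        wavelengths=panel.wavelengths,
        values=panel.values * (hi - lo) + lo,
        traits=panel.traits,
        normalized=False,
        norm_constants=None,
    )


# ---------------------------------------------------------------------------
# Genotype grouping


def build_groups(
    panel: SpectraPanel,
    E: int,
    N: int,
    missing_policy: str = "drop_genotype",
    environment_order: Sequence[str] | None = None,
) -> list[GenotypeGroup]:
    """Assemble one :class:`GenotypeGroup` of P = E*N plots per genotype.

    Member order is environment-major (all N replicates of the first
    environment, then the second, ...), with environments ordered
    lexicographically unless ``environment_order`` is given and replicates
    ordered lexicographically within an environment.  Genotypes with
    incomplete membership are dropped with a warning (``drop_genotype``) or
    raise (``error``).  The group list is sorted by genotype id.
    """
    if E < 1 or N < 1:
        raise PanelError(f"E and N must be >= 1, got E={E}, N={N}")
    if missing_policy not in ("error", "drop_genotype"):
        raise PanelError(f"unknown missing_policy {missing_policy!r}")

    envs_present = sorted(panel.meta["environment"].unique())
    if environment_order is None:
        env_order = envs_present
    else:
        env_order = list(environment_order)
        if sorted(env_order) != envs_present:
            raise PanelError(
                f"environment_order {env_order} does not match environments present {envs_present}"
            )
    if len(env_order) != E:
        raise PanelError(f"panel has {len(env_order)} environments, expected E={E}")
    env_rank = {e: i for i, e in enumerate(env_order)}

    by_key: dict[str, dict[int, list[tuple[str, int]]]] = {}
    for idx, (g, e, r) in enumerate(panel.sample_keys()):
        by_key.setdefault(g, {}).setdefault(env_rank[e], []).append((r, idx))

    groups: list[GenotypeGroup] = []
    for g in sorted(by_key):
        envs = by_key[g]
        complete = len(envs) == E and all(len(envs.get(ei, [])) == N for ei in range(E))
        if not complete:
            if missing_policy == "error":
                raise PanelError(f"genotype {g!r} has incomplete E x N membership")
            logger.warning("dropping genotype %r: incomplete E x N membership", g)
            continue
        members: list[int] = []
        for ei in range(E):
            members.extend(idx for _, idx in sorted(envs[ei]))
        groups.append(GenotypeGroup(genotype_id=g, members=tuple(members), E=E, N=N))
    return groups


def group_matrix(panel: SpectraPanel, group: GenotypeGroup) -> np.ndarray:
    """Spectra of one group as a ``[P, n_wavelengths]`` matrix in canonical order."""
    return panel.values[list(group.members)]


def stack_groups(panel: SpectraPanel, groups: Sequence[GenotypeGroup]) -> np.ndarray:
    """Spectra of all groups as ``[n_groups, P, n_wavelengths]``."""
    if not groups:
        raise PanelError("no groups supplied")
    return np.stack([group_matrix(panel, g) for g in groups])
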