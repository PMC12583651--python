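"""Variable dictionary, cohort table I/O and cohort summaries.

The study cohort is a rectangular table: one row per participant, one column
per variable, plus a ``diagnosis`` column with labels CN / EMCI / LMCI / AD.
Nineteen variables are analysed when left/right hemispheres are averaged
(merged mode); thirty-one when the six volume and six glucose-uptake regions
are kept per hemisphere (split mode).

Variable coding follows the study conventions: sex is 1 for women and 0 for
men, APOE4 is 1 when at least one allele is present, the amyloid stage is a
five-level ordinal score in {0..4}, education is integer years, and the two
cognitive composites (memory, executive function) are bounded in [-3, 3].
Missing values are a hard error: the analysis is complete-case only, because
silent imputation would change the estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

DIAGNOSIS_GROUPS = ("CN", "EMCI", "LMCI", "AD")

REGIONS = ("hipp", "caud", "put", "thal", "pcc", "prec")

REGION_FULL_NAMES = {
    "hipp": "hippocampus",
    "caud": "caudate",
    "put": "putamen",
    "thal": "thalamus",
    "pcc": "PCC",
    "prec": "precuneus",
}

ROLES = ("demographic", "cognitive", "genetic", "amyloid", "volume", "glucose")
MEASUREMENT_CLASSES = ("continuous", "discrete_count", "binary", "ordinal")

#: Table-1 group sizes of the study cohort (CN, EMCI, LMCI, AD).
DEFAULT_GROUP_SIZES = {"CN": 345, "EMCI": 297, "LMCI": 205, "AD": 175}

COGNITIVE_RANGE = (-3.0, 3.0)
EDUCATION_RANGE = (0, 25)


@dataclass(frozen=True)
class VariableSpec:
    """Typed description of one cohort column."""

    name: str
    role: str
    measurement_class: str
    levels: Optional[tuple[int, ...]] = None
    region: Optional[str] = None
    hemisphere: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for {self.name!r}")
        if self.measurement_class not in MEASUREMENT_CLASSES:
            raise ValidationError(
                f"unknown measurement class {self.measurement_class!r} for {self.name!r}"
            )
        if self.measurement_class == "binary":
            if self.levels != (0, 1):
                raise ValidationError(f"binary spec {self.name!r} must have levels (0, 1)")
        if self.measurement_class == "ordinal":
            if self.levels is None or len(self.levels) < 2:
                raise ValidationError(f"ordinal spec {self.name!r} needs ordered levels")
        if self.role in ("volume", "glucose"):
            if self.region not in REGIONS:
                raise ValidationError(f"{self.role} spec {self.name!r} must carry a region")
        elif self.region is not None:
            raise ValidationError(f"{self.role} spec {self.name!r} must not carry a region")

    @property
    def is_discrete(self) -> bool:
        """True when the column is copula-resampled during MCMC.

        Age is treated as continuous even though it is recorded discretely;
        sex, education, APOE4 and the amyloid stage are discrete.
        """
        if self.name == "age":
            return False
        return self.measurement_class in ("binary", "ordinal", "discrete_count")


@dataclass(frozen=True)
class VariableDictionary:
    """Ordered collection of variable specs (merged: 19, split: 31)."""

    specs: tuple[VariableSpec, ...]
    mode: str  # "merged" | "split"

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValidationError("variable names must be unique")
        if self.mode not in ("merged", "split"):
            raise ValidationError(f"unknown dictionary mode {self.mode!r}")
        expected = 19 if self.mode == "merged" else 31
        if len(self.specs) != expected:
            raise ValidationError(
                f"{self.mode} dictionary must have {expected} variables, got {len(self.specs)}"
            )

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def spec(self, name: str) -> VariableSpec:
        return self.specs[self.index(name)]

    @property
    def discrete_mask(self) -> np.ndarray:
        return np.array([s.is_discrete for s in self.specs], dtype=bool)

    def to_yaml(self, path) -> None:
        payload = {
            "mode": self.mode,
            "variables": [
                {
                    "name": s.name,
                    "role": s.role,
                    "measurement_class": s.measurement_class,
                    "levels": list(s.levels) if s.levels is not None else None,
                    "region": s.region,
                    "hemisphere": s.hemisphere,
                }
                for s in self.specs
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableDictionary":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        specs = tuple(
            VariableSpec(
                name=v["name"],
                role=v["role"],
                measurement_class=v["measurement_class"],
                levels=tuple(v["levels"]) if v.get("levels") else None,
                region=v.get("region"),
                hemisphere=v.get("hemisphere"),
            )
            for v in payload["variables"]
        )
        return cls(specs=specs, mode=payload["mode"])


def _base_specs() -> list[VariableSpec]:
    edu_levels = tuple(range(EDUCATION_RANGE[0], EDUCATION_RANGE[1] + 1))
    return [
        VariableSpec("age", "demographic", "continuous"),
        VariableSpec("sex", "demographic", "binary", levels=(0, 1)),
        VariableSpec("edu", "demographic", "discrete_count", levels=edu_levels),
        VariableSpec("apoe4", "genetic", "binary", levels=(0, 1)),
        VariableSpec("amyloid", "amyloid", "ordinal", levels=(0, 1, 2, 3, 4)),
        VariableSpec("mem", "cognitive", "continuous"),
        VariableSpec("ef", "cognitive", "continuous"),
    ]


def merged_dictionary() -> VariableDictionary:
    """The 19-variable dictionary with left/right regions averaged."""
    specs = _base_specs()
    for role, prefix in (("volume", "v"), ("glucose", "g")):
        for region in REGIONS:
            specs.append(
                VariableSpec(f"{prefix}_{region}", role, "continuous", region=region, hemisphere="merged")
            )
    return VariableDictionary(specs=tuple(specs), mode="merged")


def split_dictionary() -> VariableDictionary:
    """The 31-variable dictionary with separate left/right regions."""
    specs = _base_specs()
    for role, prefix in (("volume", "v"), ("glucose", "g")):
        for region in REGIONS:
            for hemi in ("l", "r"):
                specs.append(
                    VariableSpec(
                        f"{prefix}_{region}_{hemi}",
                        role,
                        "continuous",
                        region=region,
                        hemisphere={"l": "left", "r": "right"}[hemi],
                    )
                )
    return VariableDictionary(specs=tuple(specs), mode="split")


@dataclass
class CohortTable:
    """Validated n x p mixed-type cohort with diagnosis labels."""

    values: pd.DataFrame
    diagnosis: pd.Series
    dictionary: VariableDictionary

    def __post_init__(self) -> None:
        self.values = self.values.loc[:, self.dictionary.names]
        validate_cohort(self.values, self.diagnosis, self.dictionary)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def p(self) -> int:
        return len(self.dictionary)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_rows(self, mask) -> "CohortTable":
        mask = np.asarray(mask)
        return CohortTable(
            values=self.values.loc[mask].reset_index(drop=True),
            diagnosis=self.diagnosis.loc[mask].reset_index(drop=True),
            dictionary=self.dictionary,
        )

    def group(self, label: str) -> "CohortTable":
        return self.subset_rows((self.diagnosis == label).to_numpy())


def validate_cohort(values: pd.DataFrame, diagnosis: pd.Series, dictionary: VariableDictionary) -> None:
    if len(values) != len(diagnosis):
        raise ValidationError("diagnosis length does not match table length")
    bad_dx = ~diagnosis.isin(DIAGNOSIS_GROUPS)
    if bad_dx.any():
        row = int(np.flatnonzero(bad_dx.to_numpy())[0])
        raise ValidationError(f"unknown diagnosis label in row {row}")
    for spec in dictionary:
        col = values[spec.name]
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValidationError(f"missing value in column {spec.name!r} at row {row}")
        arr = col.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            row = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValidationError(f"non-finite value in column {spec.name!r} at row {row}")
        if spec.levels is not None:
            ok = np.isin(arr, np.asarray(spec.levels, dtype=float))
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise ValidationError(
                    f"out-of-range code {arr[row]!r} in column {spec.name!r} at row {row}"
                )
        if spec.role == "cognitive":
            lo, hi = COGNITIVE_RANGE
            out = (arr < lo) | (arr > hi)
            if out.any():
                row = int(np.flatnonzero(out)[0])
                raise ValidationError(
                    f"cognitive composite {spec.name!r} outside [-3, 3] at row {row}"
                )


def load_cohort(path, dictionary: VariableDictionary) -> CohortTable:
    """Read and validate a cohort CSV against a variable dictionary.

    The file must contain a header naming every dictionary variable plus a
    ``diagnosis`` column; column order in the file is irrelevant — the table
    is returned in dictionary order.
    """
    df = pd.read_csv(path)
    missing = [n for n in dictionary.names + ["diagnosis"] if n not in df.columns]
    if missing:
        raise ValidationError(f"cohort file {path} is missing column(s): {missing}")
    values = df.loc[:, dictionary.names].reset_index(drop=True)
    diagnosis = df["diagnosis"].astype(str).reset_index(drop=True)
    return CohortTable(values=values, diagnosis=diagnosis, dictionary=dictionary)


def write_cohort(table: CohortTable, path) -> None:
    out = table.values.copy()
    out["diagnosis"] = table.diagnosis.to_numpy()
    out.to_csv(path, index=False)


def merge_hemispheres(table: CohortTable) -> CohortTable:
    """Average left/right region columns, mapping a split table to merged.

    Non-region variables pass through unchanged; each region/modality pair
    becomes the unweighted mean of its left and right columns.
    """
    if table.dictionary.mode != "split":
        raise ValidationError("merge_hemispheres requires a split-mode (31-variable) table")
    merged = merged_dictionary()
    cols: dict[str, np.ndarray] = {}
    for spec in merged:
        if spec.region is None:
            cols[spec.name] = table.values[spec.name].to_numpy()
        else:
            left = table.values[f"{spec.name}_l"].to_numpy(dtype=float)
            right = table.values[f"{spec.name}_r"].to_numpy(dtype=float)
            cols[spec.name] = 0.5 * (left + right)
    values = pd.DataFrame(cols, columns=merged.names)
    return CohortTable(values=values, diagnosis=table.diagnosis.copy(), dictionary=merged)


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Per-diagnosis-group demographics in the style of a Table 1.

    Reports sample size, percent female, and mean (SD) of age, education and
    the two cognitive composites, with a total row whose size is the sum of
    the group sizes. Empty groups report NaN statistics, never crash.
    """
    rows = []
    for label in DIAGNOSIS_GROUPS + ("total",):
        sub = table if label == "total" else table.group(label)
        row: dict[str, object] = {"group": label, "n": sub.n}
        if sub.n == 0:
            row.update({k: np.nan for k in (
                "female_pct", "age_mean", "age_sd", "edu_mean", "edu_sd",
                "mem_mean", "mem_sd", "ef_mean", "ef_sd")})
        else:
            row["female_pct"] = 100.0 * sub.values["sex"].mean()
            for var in ("age", "edu", "mem", "ef"):
                arr = sub.values[var].to_numpy(dtype=float)
                row[f"{var}_mean"] = float(arr.mean())
                row[f"{var}_sd"] = float(arr.std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
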