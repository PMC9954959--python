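"""Synthetic generator for coded thyroid-nodule tables.

The clinical table behind the study design — 398 histopathologically
verified nodules (284 malignant, 114 benign) scored by a sonographer on 27
sonographic signs — is not publicly deposited.  This module generates
labeled tables with the same schema: each sign P1..P27 takes integer
sub-feature codes from its catalogue range (P1, the nodule size in mm, and
P10, the anteroposterior/transverse diameter ratio, are continuous), and
the sub-feature codes that the sonography literature associates with
malignancy (e.g. solid composition, marked hypoechogenicity,
taller-than-wide shape, irregular margins, punctate microcalcifications,
capsule interruption, suspicious or metastatic lymph nodes) are enriched in
malignant rows.

The single effect-size knob is ``risk_lift``: for a sign with valid codes V
and high-risk set H, malignant rows draw from
``lift * uniform(H) + (1 - lift) * uniform(V)`` and benign rows from
``lift * uniform(V minus H) + (1 - lift) * uniform(V)``.  At ``risk_lift=0``
every sign is uniform in both classes, so labels are independent of the
signs.  Signs with no literature consensus keep empty high-risk sets and
stay uniform at any lift.  Signs are drawn conditionally independent given
the class — real inter-sign correlations are not emulated.

Conditional signs (P7–P9, P12–P14, P19 are scored "if any") emit code 0
when their gating sign is absent; gating is minimal and documented, not a
claim of clinical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignSpec",
    "SignSchema",
    "GeneratorConfig",
    "NoduleTable",
    "build_schema",
    "generate",
    "write_table",
    "read_table",
]

LABELS = ("benign", "malignant")


@dataclass(frozen=True)
class SignSpec:
    """One sonographic sign: its code range, risk set, and gating rule."""

    notation: str
    name: str
    kind: str                       # "continuous" or "ordinal"
    codes: tuple[int, ...] = ()
    high_risk: frozenset = frozenset()
    #: (parent notation, parent codes under which this sign is applicable);
    #: None for unconditional signs.
    gate: tuple[str, frozenset] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal"):
            raise ValueError(f"unknown sign kind {self.kind!r}")
        if self.kind == "ordinal" and not self.codes:
            raise ValueError(f"{self.notation}: ordinal sign needs codes")
        if not self.high_risk <= set(self.codes):
            raise ValueError(f"{self.notation}: high-risk codes outside range")


@dataclass(frozen=True)
class SignSchema:
    """The full ordered 27-sign catalogue."""

    signs: tuple[SignSpec, ...]

    def __getitem__(self, notation: str) -> SignSpec:
        for s in self.signs:
            if s.notation == notation:
                return s
        raise KeyError(notation)

    @property
    def notations(self) -> list[str]:
        return [s.notation for s in self.signs]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-sized defaults: 398 nodules, 284 of them malignant."""

    n_total: int = 398
    n_malignant: int = 284
    risk_lift: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_malignant <= self.n_total:
            raise ValueError("need 0 <= n_malignant <= n_total")
        if not 0 <= self.risk_lift <= 1:
            raise ValueError("risk_lift must lie in [0, 1]")


@dataclass(frozen=True)
class NoduleTable:
    """Labeled nodule records: sign columns P1..P27 plus 0/1 labels."""

    signs: pd.DataFrame
    labels: np.ndarray              # 0 = benign, 1 = malignant

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.labels):
            raise ValueError("signs and labels disagree on length")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        """Raw feature matrix (n, 27) in catalogue code units."""
        return self.signs.to_numpy(dtype=float)

    def subset_signs(self, notations: list[str]) -> "NoduleTable":
        """Keep only the named sign columns (e.g. a top-13 reduction)."""
        return NoduleTable(signs=self.signs[list(notations)].copy(),
                           labels=self.labels.copy())


def build_schema() -> SignSchema:
    """The 27-sign catalogue with literature high-risk sub-feature sets.

    High-risk sets: P2 completely solid / solid with microcysts {1, 2};
    P3 markedly hypoechoic / hypoechoic {2, 3}; P4 taller-than-wide {2};
    P5 ill-defined or irregular margins {1, 3, 4, 5}; P6 punctate
    microcalcification {2}; P9 hypoechoic inner echo {3}; P14 capsule
    interruption or gross extrathyroidal extension {2, 3}; P19 solid-
    component microechogenicity {2, 4}; P25 suspicious or typical
    metastatic central nodes {5..10}; P27 suspicious/typical lateral nodes
    {2, 3}.  All other signs carry no consensus and get empty sets.
    """
    r = lambda k: tuple(range(1, k + 1))
    f = frozenset
    signs = (
        SignSpec("P1", "Size (mm)", "continuous"),
        SignSpec("P2", "Composition", "ordinal", r(9), f({1, 2})),
        SignSpec("P3", "Echogenicity", "ordinal", r(9), f({2, 3})),
        SignSpec("P4", "Shape (AP/transverse increased)", "ordinal", r(2), f({2})),
        SignSpec("P5", "Edge", "ordinal", r(8), f({1, 3, 4, 5})),
        SignSpec("P6", "Calcification / microechogenicity pattern", "ordinal",
                 r(14), f({2})),
        SignSpec("P7", "Distribution of linear microechogenicity", "ordinal",
                 r(3), gate=("P6", f({3, 4, 10, 13}))),
        SignSpec("P8", "Number/distribution of internal microechogenicity",
                 "ordinal", r(4), gate=("P6", f({2, 4, 5, 10, 12, 13}))),
        SignSpec("P9", "Inner echo with incomplete peripheral calcification",
                 "ordinal", r(3), f({3}), gate=("P6", f({8, 10}))),
        SignSpec("P10", "AP/horizontal diameter ratio", "continuous"),
        SignSpec("P11", "Capsule relationship", "ordinal", r(9)),
        SignSpec("P12", "Perimeter fraction contacting capsule", "ordinal",
                 r(4), gate=("P11", f(range(2, 10)))),
        SignSpec("P13", "Abutment of thyroid capsule", "ordinal", r(3),
                 gate=("P11", f(range(2, 10)))),
        SignSpec("P14", "Interruption in echogenic capsule", "ordinal", r(4),
                 f({2, 3}), gate=("P11", f(range(2, 10)))),
        SignSpec("P15", "Halo", "ordinal", r(4)),
        SignSpec("P16", "Blood flow pattern", "ordinal", r(4)),
        SignSpec("P17", "Reflective shadowing in solid nodule", "ordinal", r(2)),
        SignSpec("P18", "Posterior acoustic enhancement", "ordinal", r(2)),
        SignSpec("P19", "Solid component features in cystic nodule", "ordinal",
                 r(4), f({2, 4}), gate=("P2", f(range(2, 9)))),
        SignSpec("P20", "Localization", "ordinal", r(4)),
        SignSpec("P21", "Localization within thyroid lobe", "ordinal", r(4)),
        SignSpec("P22", "Solitary/multinodular", "ordinal", r(2)),
        SignSpec("P23", "Signs suggesting chronic thyroiditis", "ordinal", r(3)),
        SignSpec("P24", "Free microechogenicity in parenchyma", "ordinal", r(2)),
        SignSpec("P25", "Central lymph node size/features", "ordinal", r(10),
                 f({5, 6, 7, 8, 9, 10})),
        SignSpec("P26", "Number of central lymph nodes", "ordinal", r(3)),
        SignSpec("P27", "Lateral metastatic lymph node", "ordinal", r(3),
                 f({2, 3})),
    )
    assert len(signs) == 27
    return SignSchema(signs=signs)


def _class_pmf(spec: SignSpec, malignant: bool, lift: float) -> np.ndarray:
    """Categorical over spec.codes for one class."""
    v = np.array(spec.codes)
    base = np.full(v.size, 1.0 / v.size)
    if not spec.high_risk or lift == 0:
        return base
    hr = np.isin(v, list(spec.high_risk))
    if malignant:
        focus = hr / hr.sum()
    else:
        focus = (~hr) / (~hr).sum()
    return lift * focus + (1 - lift) * base


def generate(schema: SignSchema, cfg: GeneratorConfig) -> NoduleTable:
    """Draw a labeled nodule table; deterministic for a given seed.

    Labels are drawn first (exactly ``n_malignant`` malignant, row order
    shuffled).  Ordinal signs follow the class-conditional categorical
    described in the module docstring.  Size P1 is log-normal with median
    12 mm and 0.5 log-units spread in both classes; the ratio P10 is
    normal(0.85, 0.15) for benign rows with the malignant mean lifted
    toward taller-than-wide in proportion to ``risk_lift`` (1.05 at full
    lift), so that at zero lift the classes coincide.  Conditional signs
    are zeroed wherever their gate code is absent.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.zeros(cfg.n_total, dtype=int)
    labels[: cfg.n_malignant] = 1
    rng.shuffle(labels)
    mal = labels == 1

    cols: dict[str, np.ndarray] = {}
    for spec in schema.signs:
        if spec.notation == "P1":
            vals = np.exp(rng.normal(np.log(12.0), 0.5, size=cfg.n_total))
            cols["P1"] = np.round(vals, 1)
            continue
        if spec.notation == "P10":
            mean = np.where(mal, 0.85 + 0.20 * cfg.risk_lift, 0.85)
            vals = rng.normal(mean, 0.15)
            cols["P10"] = np.round(np.maximum(vals, 0.05), 2)
            continue
        v = np.array(spec.codes)
        out = np.empty(cfg.n_total, dtype=int)
        for is_mal in (False, True):
            sel = mal == is_mal
            pmf = _class_pmf(spec, is_mal, cfg.risk_lift)
            out[sel] = rng.choice(v, size=sel.sum(), p=pmf)
        cols[spec.notation] = out

    for spec in schema.signs:
        if spec.gate is not None:
            parent, active = spec.gate
            absent = ~np.isin(cols[parent], list(active))
            cols[spec.notation] = np.where(absent, 0, cols[spec.notation])

    return NoduleTable(signs=pd.DataFrame(cols, columns=schema.notations),
                       labels=labels)


# ---------------------------------------------------------------------------
# CSV round trip


def write_table(table: NoduleTable, path) -> None:
    """CSV with header ``P1,...,P27,label``; labels written as words."""
    df = table.signs.copy()
    df["label"] = np.array(LABELS)[table.labels]
    df.to_csv(path, index=False)


def read_table(path, schema: SignSchema | None = None) -> NoduleTable:
    """Read and validate a nodule CSV against the schema.

    Rejects unknown or missing columns, out-of-range codes (0 is accepted
    only for conditional signs), and unknown labels; errors name the
    offending row and column.
    """
    schema = schema or build_schema()
    df = pd.read_csv(path)
    expected = schema.notations + ["label"]
    if list(df.columns) != expected:
        raise ValueError(
            f"bad column set: expected {expected}, got {list(df.columns)}"
        )
    bad = ~df["label"].isin(LABELS)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"row {row}: unknown label {df['label'].iloc[row]!r}")
    for spec in schema.signs:
        col = df[spec.notation]
        if spec.kind == "continuous":
            if (col <= 0).any():
                row = int(np.argmax((col <= 0).to_numpy()))
                raise ValueError(
                    f"row {row}, sign {spec.notation}: "
                    f"non-positive value {col.iloc[row]}"
                )
            continue
        allowed = set(spec.codes) | ({0} if spec.gate is not None else set())
        invalid = ~col.isin(allowed)
        if invalid.any():
            row = int(np.argmax(invalid.to_numpy()))
            raise ValueError(
                f"row {row}, sign {spec.notation}: code {col.iloc[row]} "
                f"outside {sorted(allowed)}"
            )
    labels = (df["label"] == "malignant").to_numpy(dtype=int)
    return NoduleTable(signs=df[schema.notations].copy(), labels=labels)
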