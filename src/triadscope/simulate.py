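"""Synthetic classroom sociometric studies.

Generates rosters, ordinal contact matrices, co-drinking nomination networks
and AUDIT responses with the statistical structure the analysis assumes:
directed ties with reciprocity and gender homophily, triadic closure sweeps,
ordinal intensities from a latent tie strength, rural/urban risk prevalence
gradients, and nominations concentrated among at-risk friends.

Generation order per classroom: genders → base ties (base probability,
+homophily boost if same gender, +reciprocity boost if the reverse tie is
already present) → closure sweeps (each open two-path i→k→j is closed with
``closure_prob``) → ordinal intensities (non-ties are 1; ties map to 2–5 via
latent-strength cuts) → risk status (Bernoulli, rural shift) → consumption
nominations (over contact ties, probability by joint risk status) → AUDIT
items partitioned to match risk status under the scoring threshold.

Each classroom draws from its own pseudo-random stream derived from the
study seed and the classroom's position, so one classroom's output does not
depend on the others.

The default configuration is the **paper-shaped preset**: 6 rural + 4 urban
classrooms totalling 195 students, 54% female, rural risk prevalence above
urban.  It mimics the shape of the survey design the pipeline targets, with
no claim of matching any particular real dataset's generating process.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import UsageError, ValidationError
from .model import AUDIT_ITEM_SETS, Actor, AuditResponse, BinaryNetwork, ContactMatrix
from .stats import DEFAULT_AUDIT_THRESHOLD

PRESET_NAMES = ("paper_shaped", "null_model", "high_closure")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the classroom-network generator.

    Probabilities are additive boosts clipped to [0, 1]; ``intensity_cuts``
    are strictly increasing latent-strength thresholds in (0, 1) mapping a
    tie's latent uniform draw to ordinal ratings 2/3/4/5.
    """

    n_classrooms_rural: int = 6
    n_classrooms_urban: int = 4
    class_size_range: tuple[int, int] = (18, 35)
    class_sizes_rural: tuple[int, ...] | None = (17, 17, 17, 17, 16, 16)
    class_sizes_urban: tuple[int, ...] | None = (24, 24, 24, 23)
    p_female: float = 0.54
    base_tie_prob: float = 0.12
    reciprocity_boost: float = 0.35
    homophily_boost: float = 0.15
    closure_prob: float = 0.15
    closure_sweeps: int = 2
    intensity_cuts: tuple[float, float, float] = (0.45, 0.75, 0.92)
    risk_prevalence: float = 0.41
    risk_setting_effect: float = 0.05
    drink_tie_prob_both_risk: float = 0.70
    drink_tie_prob_otherwise: float = 0.15
    audit_threshold: int = DEFAULT_AUDIT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "p_female": self.p_female, "base_tie_prob": self.base_tie_prob,
            "reciprocity_boost": self.reciprocity_boost,
            "homophily_boost": self.homophily_boost, "closure_prob": self.closure_prob,
            "risk_prevalence": self.risk_prevalence,
            "risk_setting_effect": self.risk_setting_effect,
            "drink_tie_prob_both_risk": self.drink_tie_prob_both_risk,
            "drink_tie_prob_otherwise": self.drink_tie_prob_otherwise,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.class_size_range
        if not (4 <= lo <= hi <= 60):
            raise ValidationError(f"class_size_range must lie within [4, 60], got {lo}-{hi}")
        c1, c2, c3 = self.intensity_cuts
        if not 0 < c1 < c2 < c3 < 1:
            raise ValidationError(f"intensity_cuts must be strictly increasing in (0,1), got {self.intensity_cuts}")
        for sizes in (self.class_sizes_rural, self.class_sizes_urban):
            if sizes is not None and any(not 4 <= s <= 60 for s in sizes):
                raise ValidationError(f"explicit class sizes must lie within [4, 60], got {sizes}")
        if self.closure_sweeps < 0:
            raise ValidationError("closure_sweeps must be >= 0")


@dataclass
class SyntheticStudy:
    actors: list[Actor]
    audits: list[AuditResponse]
    contact_matrices: dict[str, ContactMatrix]
    nomination_networks: dict[str, BinaryNetwork]
    true_params: GeneratorConfig

    @property
    def classrooms(self) -> list[str]:
        return list(self.contact_matrices)


def _classroom_sizes(cfg: GeneratorConfig, rng: np.random.Generator) -> list[tuple[str, str, int]]:
    """(classroom label, setting, size) triples in a fixed order."""
    out = []
    for setting, count, explicit in (
        ("rural", cfg.n_classrooms_rural, cfg.class_sizes_rural),
        ("urban", cfg.n_classrooms_urban, cfg.class_sizes_urban),
    ):
        prefix = setting[0].upper()
        for k in range(count):
            if explicit is not None:
                if len(explicit) != count:
                    raise ValidationError(
                        f"{count} {setting} classrooms but {len(explicit)} explicit sizes"
                    )
                size = int(explicit[k])
            else:
                lo, hi = cfg.class_size_range
                size = int(rng.integers(lo, hi + 1))
            out.append((f"{prefix}{k + 1:02d}", setting, size))
    return out


def _draw_audit_items(
    total: int, rng: np.random.Generator
) -> tuple[int, ...]:
    """Partition a target AUDIT total across the 10 items within item ranges.

    Items 9 and 10 only take even values, so their joint contribution keeps
    the required parity; any total 0-40 is feasible.
    """
    if not 0 <= total <= 40:
        raise ValidationError(f"AUDIT total must be 0-40, got {total}")
    items = []
    remaining = total
    sets = list(AUDIT_ITEM_SETS)
    for pos, allowed in enumerate(sets):
        rest = sets[pos + 1:]
        max_rest = sum(max(s) for s in rest)
        # once only the even-valued items 9-10 remain, the residual must be even
        evens_only = all(s == frozenset({0, 2, 4}) for s in rest)
        feasible = [
            v for v in sorted(allowed)
            if 0 <= remaining - v <= max_rest
            and not (evens_only and (remaining - v) % 2)
        ]
        value = int(rng.choice(feasible))
        items.append(value)
        remaining -= value
    assert remaining == 0
    return tuple(items)


def _generate_classroom(
    label: str, setting: str, size: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[Actor], list[AuditResponse], ContactMatrix, BinaryNetwork]:
    ids = [f"{label}_s{k + 1:02d}" for k in range(size)]
    genders = np.where(rng.random(size) < cfg.p_female, "female", "male")
    ages = rng.choice([16, 17, 18, 19], size=size, p=[0.35, 0.40, 0.20, 0.05])
    actors = [
        Actor(id=i, gender=g, age=int(a), classroom=label, setting=setting)
        for i, g, a in zip(ids, genders, ages)
    ]

    # base ties, row-major pair order so the reverse tie of (i, j) with i > j
    # is already decided when the reciprocity boost applies
    adj = np.zeros((size, size), dtype=int)
    same_gender = genders[:, None] == genders[None, :]
    for i in range(size):
        for j in range(size):
            if i == j:
                continue
            p = cfg.base_tie_prob
            if same_gender[i, j]:
                p += cfg.homophily_boost
            if adj[j, i]:
                p += cfg.reciprocity_boost
            adj[i, j] = rng.random() < min(1.0, p)

    for _ in range(cfg.closure_sweeps):
        reach2 = (adj @ adj) > 0          # i→k→j for some k
        np.fill_diagonal(reach2, False)
        open_pairs = np.argwhere(reach2 & (adj == 0))
        if len(open_pairs):
            close = rng.random(len(open_pairs)) < cfg.closure_prob
            for (i, j), c in zip(open_pairs, close):
                if c:
                    adj[i, j] = 1

    values = np.ones((size, size), dtype=int)
    latent = rng.random((size, size))
    c1, c2, c3 = cfg.intensity_cuts
    ordinal = 2 + (latent >= c1) + (latent >= c2) + (latent >= c3)
    values[adj == 1] = ordinal[adj == 1]
    np.fill_diagonal(values, 1)
    matrix = ContactMatrix(classroom=label, actor_order=ids, values=values)

    p_risk = cfg.risk_prevalence + (cfg.risk_setting_effect if setting == "rural" else 0.0)
    at_risk = rng.random(size) < min(1.0, p_risk)

    both_risk = at_risk[:, None] & at_risk[None, :]
    p_nom = np.where(both_risk, cfg.drink_tie_prob_both_risk, cfg.drink_tie_prob_otherwise)
    nominations = ((rng.random((size, size)) < p_nom) & (adj == 1)).astype(int)
    np.fill_diagonal(nominations, 0)
    nomination_net = BinaryNetwork(
        classroom=label, actor_order=ids, adjacency=nominations, layer="consumption"
    )

    thr = cfg.audit_threshold
    audits = []
    for actor_id, risky in zip(ids, at_risk):
        if risky:
            total = min(40, thr + int(rng.binomial(12, 0.30)))
        else:
            total = int(rng.binomial(thr - 1, 0.40)) if thr > 1 else 0
        audits.append(AuditResponse(actor_id=actor_id, items=_draw_audit_items(total, rng)))

    return actors, audits, matrix, nomination_net


def generate_study(cfg: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate a full multi-classroom study, deterministic given the seed."""
    cfg = cfg or GeneratorConfig()
    layout_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    actors: list[Actor] = []
    audits: list[AuditResponse] = []
    matrices: dict[str, ContactMatrix] = {}
    nominations: dict[str, BinaryNetwork] = {}
    for position, (label, setting, size) in enumerate(_classroom_sizes(cfg, layout_rng)):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, position)))
        a, q, m, nom = _generate_classroom(label, setting, size, cfg, rng)
        actors += a
        audits += q
        matrices[label] = m
        nominations[label] = nom
    return SyntheticStudy(
        actors=actors, audits=audits, contact_matrices=matrices,
        nomination_networks=nominations, true_params=cfg,
    )


def summarize_truth(study: SyntheticStudy) -> dict:
    """Generator-truth summary computed with the pipeline's own operations."""
    from .dichotomize import dichotomize
    from .stats import risk_proportions, score_audit
    from .triads import census

    cfg = study.true_params
    same_gender_ties = total_ties = mutual = 0
    shares = {}
    risk_density_num = risk_density_den = other_num = other_den = 0
    gender = {a.id: a.gender for a in study.actors}
    risk = {
        c.actor_id: c.at_risk
        for c in (score_audit(r, cfg.audit_threshold) for r in study.audits)
    }
    for label, matrix in study.contact_matrices.items():
        net = dichotomize(matrix, "minimum")
        adj = net.adjacency
        ids = net.actor_order
        g = np.array([gender[i] for i in ids])
        same = g[:, None] == g[None, :]
        total_ties += adj.sum()
        same_gender_ties += (adj * same).sum()
        mutual += (adj * adj.T).sum()  # counts each mutual dyad twice
        shares[label] = census(net).transitive_share
        at_risk = np.array([risk[i] for i in ids])
        both = at_risk[:, None] & at_risk[None, :]
        off = ~np.eye(len(ids), dtype=bool)
        nom = study.nomination_networks[label].adjacency
        risk_density_num += nom[both & off].sum()
        risk_density_den += (both & off).sum()
        other_num += nom[~both & off].sum()
        other_den += (~both & off).sum()

    risk_table = risk_proportions(
        [score_audit(r, cfg.audit_threshold) for r in study.audits],
        actors=study.actors, by="setting",
    )
    return {
        "same_gender_tie_fraction": same_gender_ties / total_ties if total_ties else float("nan"),
        "arc_reciprocity": mutual / total_ties if total_ties else float("nan"),
        "transitive_share_per_classroom": shares,
        "mean_transitive_share": float(np.mean(list(shares.values()))),
        "risk_prevalence_by_setting": {
            row["setting"]: row["pct_at_risk"] / 100.0 for _, row in risk_table.iterrows()
        },
        "consumption_density_at_risk_pairs": risk_density_num / risk_density_den if risk_density_den else float("nan"),
        "consumption_density_other_pairs": other_num / other_den if other_den else float("nan"),
    }


def load_preset(name: str, **overrides) -> GeneratorConfig:
    """Load a named preset config (paper_shaped, null_model, high_closure)."""
    if name not in PRESET_NAMES:
        raise UsageError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    text = resources.files("triadscope").joinpath(f"presets/{name}.yaml").read_text()
    params = yaml.safe_load(text) or {}
    params.update(overrides)
    for key in ("class_size_range", "class_sizes_rural", "class_sizes_urban", "intensity_cuts"):
        if key in params and params[key] is not None:
            params[key] = tuple(params[key])
    return GeneratorConfig(**params)
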