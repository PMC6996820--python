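"""Candidate multi-location model configurations with parameter sharing.

A :class:`ModelConfig` assigns one functional form to each survey location
and, for every dynamic parameter, a partition of the locations whose form
carries that parameter: locations in one block share a single free value.
Error standard deviations follow a fixed convention — locations with the
same functional form share one σ_ε, locations with different forms get
separate σ_ε's — so the σ grouping is induced by the form assignment and is
not a free combinatorial axis.

The number of free parameters k of a config is the number of dynamic-
parameter blocks plus the number of σ groups; this is exactly the number of
distinct values the likelihood needs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .forms import FORM_PARAMS, FORMS

__all__ = [
    "ModelConfig",
    "enumerate_model_space",
    "config_free_parameters",
    "space_manifest",
]

PARAM_ORDER = ("lambda", "beta", "theta")

Block = tuple[str, ...]
Partition = tuple[Block, ...]


def _canon_partition(blocks: Iterable[Iterable[str]]) -> Partition:
    return tuple(sorted(tuple(sorted(b)) for b in blocks))


def _set_partitions(items: Sequence[str]):
    """All set partitions of ``items`` (Bell(n) of them), deterministically."""
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        # first in its own block
        yield ((first,),) + sub
        # first joined to each existing block
        for i in range(len(sub)):
            yield sub[:i] + ((first,) + sub[i],) + sub[i + 1 :]


@dataclass(frozen=True)
class ModelConfig:
    """Immutable assignment of forms and parameter-sharing to locations.

    ``forms``: ((location, form), ...) sorted by location.
    ``sharing``: ((param, ((loc, ...), ...)), ...) — for each dynamic
    parameter present in the config, the partition of the locations whose
    form has that parameter; stored in canonical sorted order.
    """

    forms: tuple[tuple[str, str], ...]
    sharing: tuple[tuple[str, Partition], ...]

    @classmethod
    def build(
        cls,
        forms: Mapping[str, str],
        sharing: Mapping[str, Iterable[Iterable[str]]] | None = None,
    ) -> "ModelConfig":
        """Construct and validate a config.

        ``sharing`` may omit parameters (defaulting to no sharing, i.e.
        singleton blocks) or be ``None`` for fully independent parameters.
        """
        form_items = tuple(sorted((str(l), f) for l, f in forms.items()))
        for loc, f in form_items:
            if f not in FORM_PARAMS:
                raise ValueError(f"unknown form {f!r} at location {loc!r}")
        by_param: dict[str, list[str]] = {}
        for loc, f in form_items:
            for p in FORM_PARAMS[f]:
                by_param.setdefault(p, []).append(loc)
        sharing = dict(sharing or {})
        canon: list[tuple[str, Partition]] = []
        for p in PARAM_ORDER:
            if p not in by_param:
                continue
            locs = sorted(by_param[p])
            if p in sharing:
                part = _canon_partition(sharing[p])
            else:
                part = _canon_partition([[l] for l in locs])
            covered = sorted(l for b in part for l in b)
            if covered != locs:
                raise ValueError(
                    f"sharing partition for {p!r} must cover exactly {locs}, got {covered}"
                )
            fmap = dict(form_items)
            for b in part:
                if len({fmap[l] for l in b}) > 1:
                    raise ValueError(
                        f"block {b} shares {p!r} across locations with different forms"
                    )
            canon.append((p, part))
        extra = set(sharing) - {p for p, _ in canon}
        if extra:
            raise ValueError(f"sharing given for parameters not in the config: {sorted(extra)}")
        return cls(forms=form_items, sharing=tuple(canon))

    # -- structure ---------------------------------------------------------

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.forms)

    @property
    def form_map(self) -> dict[str, str]:
        return dict(self.forms)

    def form_at(self, location: str) -> str:
        return self.form_map[location]

    @property
    def sigma_groups(self) -> Partition:
        """Partition of locations into error-variance groups (by form)."""
        groups: dict[str, list[str]] = {}
        for loc, f in self.forms:
            groups.setdefault(f, []).append(loc)
        return _canon_partition(groups.values())

    @property
    def sharing_map(self) -> dict[str, Partition]:
        return dict(self.sharing)

    # -- free parameters ---------------------------------------------------

    @staticmethod
    def slot_name(param: str, block: Iterable[str]) -> str:
        return f"{param}@{'+'.join(sorted(block))}"

    @property
    def dynamic_slots(self) -> tuple[tuple[str, Block], ...]:
        """Ordered (param, block) pairs, one per free dynamic value."""
        out = []
        for p, part in self.sharing:
            for b in part:
                out.append((p, b))
        return tuple(out)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Stable human-readable slot names, dynamic slots then σ groups."""
        names = [self.slot_name(p, b) for p, b in self.dynamic_slots]
        names += [self.slot_name("sigma", g) for g in self.sigma_groups]
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.dynamic_slots) + len(self.sigma_groups)

    def slot_for(self, param: str, location: str) -> str:
        """Free-parameter name that feeds ``param`` at ``location``."""
        if param == "sigma":
            for g in self.sigma_groups:
                if location in g:
                    return self.slot_name("sigma", g)
            raise KeyError(location)
        for b in self.sharing_map[param]:
            if location in b:
                return self.slot_name(param, b)
        raise KeyError(f"{param} not present at {location}")

    # -- identity / export -------------------------------------------------

    @property
    def config_id(self) -> str:
        forms = "|".join(f"{l}:{f}" for l, f in self.forms)
        parts = ";".join(
            f"{p}=" + ",".join("+".join(b) for b in part) for p, part in self.sharing
        )
        return forms + (";" + parts if parts else "")

    def sort_key(self):
        return (self.forms, self.sharing)

    def to_dict(self) -> dict:
        return {
            "id": self.config_id,
            "forms": {l: f for l, f in self.forms},
            "sharing": {p: ["+".join(b) for b in part] for p, part in self.sharing},
            "sigma_groups": ["+".join(g) for g in self.sigma_groups],
            "k": self.k,
        }


def config_free_parameters(config: ModelConfig) -> tuple[str, ...]:
    """Named free-parameter slots of ``config`` (see ``ModelConfig.free_parameters``)."""
    return config.free_parameters


def enumerate_model_space(
    locations: Sequence[str],
    scheme: str = "full",
    forms: Sequence[str] = FORMS,
) -> list[ModelConfig]:
    """Enumerate candidate configs over ``locations``.

    ``independent_only``: every assignment of a form to each location with no
    cross-location sharing (``len(forms)**L`` configs).  ``full``:
    additionally, for every group of same-form locations, every way of
    partitioning the group's locations into shared blocks, independently for
    each of the form's dynamic parameters.  Deduplicated, deterministic
    order.
    """
    if not locations:
        raise ValueError("at least one location required")
    if scheme not in ("independent_only", "full"):
        raise ValueError(f"unknown scheme {scheme!r}")
    locs = sorted(str(l) for l in locations)
    seen: set = set()
    out: list[ModelConfig] = []
    for assignment in itertools.product(forms, repeat=len(locs)):
        form_map = dict(zip(locs, assignment))
        if scheme == "independent_only":
            candidates = [ModelConfig.build(form_map)]
        else:
            # per-parameter set partitions within each same-form group
            by_param: dict[str, list[str]] = {}
            for loc, f in form_map.items():
                for p in FORM_PARAMS[f]:
                    by_param.setdefault(p, []).append(loc)
            axes: list[tuple[str, list[Partition]]] = []
            for p in PARAM_ORDER:
                if p not in by_param:
                    continue
                groups: dict[str, list[str]] = {}
                for loc in sorted(by_param[p]):
                    groups.setdefault(form_map[loc], []).append(loc)
                parts = []
                for combo in itertools.product(
                    *(list(_set_partitions(g)) for g in groups.values())
                ):
                    parts.append(_canon_partition(b for sub in combo for b in sub))
                axes.append((p, sorted(set(parts))))
            candidates = []
            for combo in itertools.product(*(parts for _, parts in axes)):
                sharing = {p: part for (p, _), part in zip(axes, combo)}
                candidates.append(ModelConfig.build(form_map, sharing))
        for cfg in candidates:
            if cfg not in seen:
                seen.add(cfg)
                out.append(cfg)
    out.sort(key=ModelConfig.sort_key)
    return out


def space_manifest(configs: Iterable[ModelConfig], path=None) -> str:
    """JSON manifest of a model space (one entry per config) for audit."""
    payload = json.dumps([c.to_dict() for c in configs], indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    return payload
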