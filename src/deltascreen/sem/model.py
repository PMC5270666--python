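"""Structural model specification.

A :class:`ModelSpec` describes a linear structural equation model over a set
of observed and latent variables in reticular-action form: collect all
variables into one vector ``v`` and write

    v = A v + u,      Cov(u) = S,

where ``A`` holds directed coefficients (factor loadings and regression
paths; entry ``A[dst, src]``) and the symmetric ``S`` holds variances,
residual variances and undirected (co)variances.  The implied covariance of
the observed sub-vector is ``F (I - A)^-1 S (I - A)^-T F'`` with ``F`` the
observed-row selector.

Free parameters carry string labels; two entries sharing a label are
constrained equal (this is also how multi-group equality constraints are
expressed).  Every entry not declared is fixed at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "SpecError"]


class SpecError(ValueError):
    """Raised for malformed or unidentified model specifications."""


@dataclass
class _Entry:
    row: str
    col: str
    free: bool
    value: float  # fixed value, or start value when free
    label: str | None = None


@dataclass
class ModelSpec:
    observed: list[str]
    latent: list[str] = field(default_factory=list)
    _paths: list[_Entry] = field(default_factory=list)
    _covs: list[_Entry] = field(default_factory=list)

    # ------------------------------------------------------------------ build
    def add_path(self, src: str, dst: str, *, free: bool = True,
                 value: float = 0.0, start: float | None = None,
                 label: str | None = None) -> "ModelSpec":
        """Directed coefficient ``src -> dst`` (loading or regression)."""
        self._check_vars(src, dst)
        if free and label is None:
            label = f"{dst}~{src}"
        v = (start if start is not None else 0.5) if free else value
        self._paths.append(_Entry(dst, src, free, v, label))
        return self

    def add_variance(self, var: str, *, free: bool = True, value: float = 0.0,
                     start: float | None = None,
                     label: str | None = None) -> "ModelSpec":
        self._check_vars(var)
        if free and label is None:
            label = f"{var}~~{var}"
        v = (start if start is not None else 1.0) if free else value
        self._covs.append(_Entry(var, var, free, v, label))
        return self

    def add_covariance(self, a: str, b: str, *, free: bool = True,
                       value: float = 0.0, start: float | None = None,
                       label: str | None = None) -> "ModelSpec":
        self._check_vars(a, b)
        if a == b:
            return self.add_variance(a, free=free, value=value, start=start,
                                     label=label)
        if free and label is None:
            label = f"{a}~~{b}"
        v = (start if start is not None else 0.0) if free else value
        self._covs.append(_Entry(a, b, free, v, label))
        return self

    def _check_vars(self, *names: str) -> None:
        for nm in names:
            if nm not in self.observed and nm not in self.latent:
                raise SpecError(f"unknown variable {nm!r}")

    # -------------------------------------------------------------- structure
    @property
    def variables(self) -> list[str]:
        return list(self.observed) + list(self.latent)

    @property
    def n_obs(self) -> int:
        return len(self.observed)

    def free_labels(self) -> list[str]:
        """Unique free-parameter labels in declaration order."""
        seen: dict[str, None] = {}
        for e in self._paths + self._covs:
            if e.free and e.label not in seen:
                seen[e.label] = None
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    def start_values(self) -> np.ndarray:
        starts = {}
        for e in self._paths + self._covs:
            if e.free and e.label not in starts:
                starts[e.label] = e.value
        return np.array([starts[l] for l in self.free_labels()], float)

    def matrices(self, theta: np.ndarray | dict) -> tuple[np.ndarray, np.ndarray]:
        """Assemble (A, S) over ``self.variables`` for parameter vector theta."""
        if isinstance(theta, dict):
            vals = theta
        else:
            vals = dict(zip(self.free_labels(), np.asarray(theta, float)))
        ix = {v: i for i, v in enumerate(self.variables)}
        nv = len(ix)
        A = np.zeros((nv, nv))
        S = np.zeros((nv, nv))
        for e in self._paths:
            A[ix[e.row], ix[e.col]] = vals[e.label] if e.free else e.value
        for e in self._covs:
            v = vals[e.label] if e.free else e.value
            S[ix[e.row], ix[e.col]] = v
            S[ix[e.col], ix[e.row]] = v
        return A, S

    def entry_index_maps(self):
        """Index lists used by the analytic gradient.

        Returns (path_entries, cov_entries) where each element is
        (label_position, row_index, col_index) for the free entries only.
        """
        ix = {v: i for i, v in enumerate(self.variables)}
        lpos = {l: k for k, l in enumerate(self.free_labels())}
        paths = [(lpos[e.label], ix[e.row], ix[e.col])
                 for e in self._paths if e.free]
        covs = [(lpos[e.label], ix[e.row], ix[e.col])
                for e in self._covs if e.free]
        return paths, covs

    # ---------------------------------------------------------- verification
    def check_identified(self) -> None:
        """Necessary conditions: every latent scaled, counting rule holds."""
        for lat in self.latent:
            scaled = any(
                (not e.free) and lat in (e.row, e.col) and e.value != 0.0
                for e in self._covs + self._paths
            )
            if not scaled:
                raise SpecError(f"latent {lat!r} has no scale constraint "
                                "(fix a loading or its variance)")
        p = self.n_obs
        if self.n_free > p * (p + 1) // 2:
            raise SpecError(
                f"{self.n_free} free parameters exceed {p * (p + 1) // 2} "
                "distinct covariance elements; model not identified")

    # --------------------------------------------------------------- utility
    def copy(self) -> "ModelSpec":
        return ModelSpec(
            list(self.observed), list(self.latent),
            [_Entry(e.row, e.col, e.free, e.value, e.label) for e in self._paths],
            [_Entry(e.row, e.col, e.free, e.value, e.label) for e in self._covs],
        )

    def relabel(self, prefix: str, shared: set[str] | None = None) -> "ModelSpec":
        """Prefix every free label except those in ``shared``.

        Used to build multi-group models: distinct prefixes keep group
        parameters separate; labels listed in ``shared`` stay common and are
        thereby equated across groups.
        """
        shared = shared or set()
        out = self.copy()
        for e in out._paths + out._covs:
            if e.free and e.label not in shared:
                e.label = f"{prefix}{e.label}"
        return out

    # ------------------------------------------------------------------ JSON
    def to_json(self) -> str:
        doc = {
            "observed": self.observed,
            "latent": self.latent,
            "paths": [vars(e) for e in self._paths],
            "covariances": [vars(e) for e in self._covs],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        doc = json.loads(text)
        spec = cls(list(doc["observed"]), list(doc["latent"]))
        spec._paths = [_Entry(**e) for e in doc["paths"]]
        spec._covs = [_Entry(**e) for e in doc["covariances"]]
        return spec
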