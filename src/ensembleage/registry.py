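"""Base-clock definitions and cross-clock CpG overlap analysis.

A *clock definition* is a published linear DNA-methylation age model: an
ordered list of CpG probe ids, one regression weight per probe, an
intercept, and an output transform (identity for most clocks; the
piecewise log/linear anti-transform for the pan-tissue Horvath clock).
Clock files are two-column CSV (``CpG,Weight``) with the intercept encoded
as a reserved row whose id is ``Intercept``.

The registry also ships a manifest describing the eight published clocks
used by the ensemble models (name, expected CpG count, transform,
provenance).  The coefficient lists themselves are not redistributed here;
``ClockRegistry.load_published`` reads them from a local directory the
user populates from the original supplements.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import FormatError, UsageError

INTERCEPT_TOKEN = "Intercept"

#: The eight published base clocks, in registry (= meta-model) order.
PUBLISHED_CLOCK_NAMES = (
    "AltumAge",
    "Han2020",
    "Hannum",
    "Horvath",
    "SkinBlood",
    "PhenoAge",
    "YingCausAge",
    "Zhang2019",
)


class Transform(str, Enum):
    """Output transform applied to a clock's linear score."""

    identity = "identity"
    horvath_log_linear = "horvath_log_linear"


@dataclass(frozen=True)
class ClockDefinition:
    """A linear epigenetic clock: age = transform(intercept + w · beta).

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"Hannum"``.
    cpg_ids : tuple of str
        Ordered Illumina probe ids (``cg``-prefixed strings).
    weights : numpy.ndarray
        One weight per CpG, applied directly to beta values.
    intercept : float
        Additive constant, in linear-score units.
    transform : Transform
        Map from linear score to years (identity for most clocks).
    platform : str
        Free-text provenance tag (array platform / training tissue).
    """

    name: str
    cpg_ids: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    transform: Transform = Transform.identity
    platform: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=float)
        )
        if self.weights.ndim != 1 or len(self.weights) != len(self.cpg_ids):
            raise UsageError(
                f"clock {self.name!r}: {len(self.cpg_ids)} CpGs but "
                f"{self.weights.size} weights"
            )
        if len(self.cpg_ids) < 1:
            raise UsageError(f"clock {self.name!r}: needs at least one CpG")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise UsageError(f"clock {self.name!r}: duplicate CpG ids")
        if not np.isfinite(self.weights).all() or not np.isfinite(
            self.intercept
        ):
            raise UsageError(f"clock {self.name!r}: non-finite coefficients")
        if not isinstance(self.transform, Transform):
            object.__setattr__(
                self, "transform", Transform(self.transform)
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def cpg_set(self) -> frozenset[str]:
        return frozenset(self.cpg_ids)


@dataclass(frozen=True)
class ExternalPredictor:
    """A non-linear base model supplied as an opaque callable.

    Used for deep-network clocks whose weights are not distributable as a
    coefficient table.  The registry keeps the CpG list (for overlap
    analysis and alignment); predictions come from ``fn``, which receives
    a samples x CpGs beta DataFrame aligned to ``cpg_ids`` and returns one
    age per sample.
    """

    name: str
    cpg_ids: tuple[str, ...]
    fn: Callable[..., np.ndarray]
    platform: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def cpg_set(self) -> frozenset[str]:
        return frozenset(self.cpg_ids)


@dataclass(frozen=True)
class OverlapHistogram:
    """counts[k] = number of CpG ids present in exactly k clocks."""

    counts: Mapping[int, int]
    n_clocks: int

    def __getitem__(self, k: int) -> int:
        return self.counts.get(k, 0)

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())


def load_clock_definition(
    path: str | Path,
    name: str | None = None,
    transform: Transform | str = Transform.identity,
    platform: str = "",
) -> ClockDefinition:
    """Read a two-column ``CpG,Weight`` CSV into a :class:`ClockDefinition`.

    Exactly one row must carry the reserved id ``Intercept``; its weight
    becomes the clock intercept.  CpG order in the file is preserved.
    """
    path = Path(path)
    cpgs: list[str] = []
    weights: list[float] = []
    intercept: float | None = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for i, row in enumerate(reader):
            if not row or not row[0].strip():
                continue
            cid, raw = row[0].strip(), row[1].strip()
            if i == 0 and cid.lower() in {"cpg", "cgid", "probe", "id"}:
                continue  # header row
            try:
                w = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric weight {raw!r} for {cid!r}"
                ) from None
            if cid == INTERCEPT_TOKEN:
                if intercept is not None:
                    raise FormatError(f"{path}: duplicate Intercept row")
                intercept = w
            else:
                cpgs.append(cid)
                weights.append(w)
    if intercept is None:
        raise FormatError(f"{path}: missing Intercept row")
    if len(set(cpgs)) != len(cpgs):
        dup = [c for c, n in Counter(cpgs).items() if n > 1]
        raise FormatError(f"{path}: duplicate CpG ids {dup[:5]}")
    return ClockDefinition(
        name=name or path.stem,
        cpg_ids=tuple(cpgs),
        weights=np.array(weights, dtype=float),
        intercept=float(intercept),
        transform=Transform(transform),
        platform=platform,
    )


def write_clock_definition(clock: ClockDefinition, path: str | Path) -> None:
    """Write a clock back to the two-column CSV dialect (lossless round-trip).

    Weights are serialized with :func:`repr` so they survive bit-exactly.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["CpG", "Weight"])
        for cid, w in zip(clock.cpg_ids, clock.weights):
            writer.writerow([cid, repr(float(w))])
        writer.writerow([INTERCEPT_TOKEN, repr(float(clock.intercept))])


def _multiplicity(
    clocks: Sequence[ClockDefinition | ExternalPredictor],
) -> Counter:
    counter: Counter = Counter()
    for clock in clocks:
        counter.update(clock.cpg_set)  # set membership: once per clock
    return counter


def overlap_histogram(
    clocks: Sequence[ClockDefinition | ExternalPredictor],
) -> OverlapHistogram:
    """How many CpGs appear in exactly k of the given clocks, k = 1..n.

    A CpG counts at most once per clock (set membership), so the histogram
    sums to the size of the union of all CpG sets.
    """
    if len(clocks) < 2:
        raise UsageError("overlap_histogram needs at least 2 clocks")
    mult = _multiplicity(clocks)
    counts = Counter(mult.values())
    return OverlapHistogram(
        counts={k: counts.get(k, 0) for k in range(1, len(clocks) + 1)},
        n_clocks=len(clocks),
    )


def cpgs_at_multiplicity(
    clocks: Sequence[ClockDefinition | ExternalPredictor], k: int
) -> set[str]:
    """CpG ids present in exactly ``k`` of the given clocks."""
    if not 1 <= k <= len(clocks):
        raise UsageError(f"multiplicity k={k} out of range 1..{len(clocks)}")
    mult = _multiplicity(clocks)
    return {cid for cid, m in mult.items() if m == k}


_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_MANIFEST = _DATA_DIR / "clock_manifest.yaml"


@dataclass
class ManifestEntry:
    name: str
    expected_n_cpgs: int
    transform: Transform
    kind: str  # "linear" | "external"
    source: str
    filename: str
    url: str | None = None
    sha256: str | None = None


@dataclass
class ClockRegistry:
    """Manifest-driven access to the published base-clock inventory.

    The manifest records, for each of the eight published clocks, its
    expected CpG count, transform and provenance.  Coefficient files are
    looked up in ``clock_dir`` (default ``~/.cache/ensembleage/clocks``);
    populate it from the original supplements, optionally via
    :meth:`fetch` when a manifest entry carries a URL.
    """

    entries: list[ManifestEntry] = field(default_factory=list)
    clock_dir: Path = field(
        default_factory=lambda: Path.home() / ".cache/ensembleage/clocks"
    )

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str | Path = DEFAULT_MANIFEST,
        clock_dir: str | Path | None = None,
    ) -> "ClockRegistry":
        with Path(manifest_path).open() as fh:
            raw = yaml.safe_load(fh)
        entries = [
            ManifestEntry(
                name=e["name"],
                expected_n_cpgs=int(e["expected_n_cpgs"]),
                transform=Transform(e.get("transform", "identity")),
                kind=e.get("kind", "linear"),
                source=e.get("source", ""),
                filename=e.get("filename", f"{e['name']}.csv"),
                url=e.get("url"),
                sha256=e.get("sha256"),
            )
            for e in raw["clocks"]
        ]
        reg = cls(entries=entries)
        if clock_dir is not None:
            reg.clock_dir = Path(clock_dir)
        return reg

    def missing(self) -> list[str]:
        """Names of manifest clocks whose coefficient file is absent."""
        return [
            e.name
            for e in self.entries
            if not (self.clock_dir / e.filename).exists()
        ]

    def fetch(self, timeout: float = 30.0) -> list[str]:
        """Download coefficient files for entries that declare a URL.

        Returns the names actually fetched.  Entries without a URL are
        skipped; files already present are kept.
        """
        import hashlib
        import urllib.request

        fetched = []
        self.clock_dir.mkdir(parents=True, exist_ok=True)
        for e in self.entries:
            target = self.clock_dir / e.filename
            if target.exists() or not e.url:
                continue
            with urllib.request.urlopen(e.url, timeout=timeout) as resp:
                payload = resp.read()
            if e.sha256:
                digest = hashlib.sha256(payload).hexdigest()
                if digest != e.sha256:
                    raise FormatError(
                        f"{e.name}: checksum mismatch ({digest})"
                    )
            target.write_bytes(payload)
            fetched.append(e.name)
        return fetched

    def load_published(
        self, external_fn: Callable[..., np.ndarray] | None = None
    ) -> list[ClockDefinition | ExternalPredictor]:
        """Load every manifest clock from ``clock_dir``, in registry order.

        Linear entries become :class:`ClockDefinition`; external entries
        (deep-network clocks distributed without a coefficient table)
        become :class:`ExternalPredictor` built from the CpG list file and
        ``external_fn``.
        """
        missing = self.missing()
        if missing:
            raise FileNotFoundError(
                f"published coefficient files not found in {self.clock_dir}: "
                f"{missing}; obtain them from the sources in the manifest"
            )
        loaded: list[ClockDefinition | ExternalPredictor] = []
        for e in self.entries:
            path = self.clock_dir / e.filename
            if e.kind == "external":
                cpgs = _read_cpg_list(path)
                if len(cpgs) != e.expected_n_cpgs:
                    raise FormatError(
                        f"{e.name}: {len(cpgs)} CpGs, expected "
                        f"{e.expected_n_cpgs}"
                    )
                loaded.append(
                    ExternalPredictor(
                        name=e.name,
                        cpg_ids=tuple(cpgs),
                        fn=external_fn or _no_external,
                        platform=e.source,
                    )
                )
            else:
                clock = load_clock_definition(
                    path, name=e.name, transform=e.transform, platform=e.source
                )
                if clock.n_cpgs != e.expected_n_cpgs:
                    raise FormatError(
                        f"{e.name}: {clock.n_cpgs} CpGs, expected "
                        f"{e.expected_n_cpgs}"
                    )
                loaded.append(clock)
        return loaded


def _read_cpg_list(path: Path) -> list[str]:
    """One CpG id per line (or first CSV column), header tolerated."""
    out = []
    with path.open() as fh:
        for line in fh:
            cid = line.split(",")[0].strip()
            if cid and cid.lower() not in {"cpg", "cgid", "probe", "id"}:
                out.append(cid)
    return out


def _no_external(betas) -> np.ndarray:
    raise UsageError(
        "this registry entry is an external predictor; supply external_fn"
    )
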