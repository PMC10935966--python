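"""Deterministic mock registries, sandbox backends and synthetic files.

Real package repositories and a container engine are deliberately absent
from the test surface: everything above the driver layer is exercised
against these fixtures instead.  All generators are pure functions of
``(spec, seed)`` — the same inputs produce byte-identical catalogs,
artifacts and file sets.

Synthetic artifacts start with a tiny self-describing header
(``PKG <name> <version>\\n``) followed by seeded pseudorandom bytes, so an
install script under test can "install" a package by recording the header
to a ledger — order assertions work without any real package manager.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ForgeError


@dataclass(frozen=True)
class PackageEntry:
    """One package of a registry spec: versions plus dependency edges."""

    name: str
    ecosystem: str
    versions: tuple[str, ...] = ("1.0",)
    depends_on: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class RegistrySpec:
    packages: tuple[PackageEntry, ...]
    artifact_size_range: tuple[int, int] = (256, 4096)
    seed: int = 0


class MockRegistry:
    """In-memory catalog + artifact store satisfying the capture Registry contract."""

    def __init__(self, spec: RegistrySpec):
        self.spec = spec
        self._index: dict[tuple[str, str], PackageEntry] = {}
        seen: set[tuple[str, str, str]] = set()
        for entry in spec.packages:
            for v in entry.versions:
                key3 = (entry.name, entry.ecosystem, v)
                if key3 in seen:
                    raise ForgeError(f"duplicate package entry: {key3}")
                seen.add(key3)
            self._index[(entry.name, entry.ecosystem)] = entry
        self._artifacts: dict[tuple[str, str, str], tuple[str, bytes]] = {}
        lo, hi = spec.artifact_size_range
        if lo < 0 or hi < lo:
            raise ForgeError(f"bad artifact size range: {spec.artifact_size_range}")
        for entry in spec.packages:
            for v in entry.versions:
                rng = random.Random(f"{spec.seed}/{entry.ecosystem}/{entry.name}/{v}")
                size = rng.randint(lo, hi)
                header = f"PKG {entry.name} {v}\n".encode()
                body = rng.randbytes(max(0, size - len(header)))
                fname = _artifact_filename(entry.name, entry.ecosystem, v)
                self._artifacts[(entry.name, entry.ecosystem, v)] = (fname, header + body)

    # Registry protocol -----------------------------------------------------
    def versions(self, name: str, ecosystem: str) -> list[str]:
        entry = self._index.get((name, ecosystem))
        return list(entry.versions) if entry else []

    def dependencies(self, name: str, ecosystem: str, version: str) -> list[tuple[str, str]]:
        entry = self._index.get((name, ecosystem))
        if entry is None or version not in entry.versions:
            raise ForgeError(f"unknown package version {ecosystem}:{name}=={version}")
        return list(entry.depends_on)

    def artifact(self, name: str, ecosystem: str, version: str) -> tuple[str, bytes]:
        try:
            return self._artifacts[(name, ecosystem, version)]
        except KeyError:
            raise ForgeError(f"no artifact for {ecosystem}:{name}=={version}")

    # snapshot format -------------------------------------------------------
    def to_json(self) -> str:
        d = {
            "seed": self.spec.seed,
            "artifact_size_range": list(self.spec.artifact_size_range),
            "packages": [
                {
                    "name": e.name,
                    "ecosystem": e.ecosystem,
                    "versions": list(e.versions),
                    "depends_on": [list(dep) for dep in e.depends_on],
                }
                for e in self.spec.packages
            ],
        }
        return json.dumps(d, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "MockRegistry":
        d = json.loads(text)
        spec = RegistrySpec(
            packages=tuple(
                PackageEntry(
                    name=p["name"],
                    ecosystem=p["ecosystem"],
                    versions=tuple(p["versions"]),
                    depends_on=tuple((n, e) for n, e in p["depends_on"]),
                )
                for p in d["packages"]
            ),
            artifact_size_range=tuple(d["artifact_size_range"]),
            seed=d["seed"],
        )
        return cls(spec)


def _artifact_filename(name: str, ecosystem: str, version: str) -> str:
    ext = {
        "pypi-like": "whl",
        "cran-like": "tar.gz",
        "bioconductor-like": "tar.gz",
        "conda": "conda",
        "bioconda": "conda",
        "apt": "deb",
        "source-host": "src.tar.gz",
    }[ecosystem]
    return f"{name}-{version}.{ext}"


def build_mock_registry(spec: RegistrySpec) -> MockRegistry:
    """Materialize a catalog + artifact store from a registry spec."""
    return MockRegistry(spec)


def random_registry_spec(
    seed: int,
    n_packages: int = 8,
    ecosystem: str = "pypi-like",
    max_deps: int = 3,
    artifact_size_range: tuple[int, int] = (200, 4000),
) -> RegistrySpec:
    """A random DAG-shaped registry: package i may depend only on earlier packages."""
    rng = random.Random(seed)
    names = []
    while len(names) < n_packages:
        name = "".join(rng.choice(string.ascii_lowercase) for _ in range(6))
        if name not in names:
            names.append(name)
    entries = []
    for i, name in enumerate(names):
        k = rng.randint(0, min(max_deps, i))
        deps = tuple((d, ecosystem) for d in sorted(rng.sample(names[:i], k)))
        n_versions = rng.randint(1, 3)
        versions = tuple(f"{maj}.{rng.randint(0, 9)}" for maj in range(1, n_versions + 1))
        entries.append(
            PackageEntry(name=name, ecosystem=ecosystem, versions=versions, depends_on=deps)
        )
    return RegistrySpec(
        packages=tuple(entries), artifact_size_range=artifact_size_range, seed=seed
    )


def make_synthetic_files(
    sizes: Sequence[int], seed: int, prefix: str = "artifacts/file"
) -> list[tuple[str, bytes]]:
    """Files of exactly the requested sizes with seeded pseudorandom content."""
    out: list[tuple[str, bytes]] = []
    for i, size in enumerate(sizes):
        if size < 0:
            raise ForgeError(f"negative file size: {size}")
        rng = random.Random(f"{seed}/{i}")
        out.append((f"{prefix}{i:04d}.bin", rng.randbytes(size)))
    return out


class MockSandboxBackend:
    """A counting, failure-injectable stand-in for the dummy container.

    ``fail_on`` is a package name whose fetch command exits non-zero, for
    exercising the failure/cleanup contract.  ``live_sessions`` counts
    sessions started but not yet destroyed.
    """

    def __init__(self, registry: MockRegistry, fail_on: Optional[str] = None):
        self.registry = registry
        self.fail_on = fail_on
        self.live_sessions = 0
        self.total_sessions = 0

    def start(self, base_image_ref: str) -> dict:
        self.live_sessions += 1
        self.total_sessions += 1
        return {"base": base_image_ref, "files": {}, "log": []}

    def run(self, session: dict, command: str) -> tuple[int, str]:
        parts = command.split()
        if len(parts) == 4 and parts[0] == "fetch":
            _, eco, name, version = parts
            if name == self.fail_on:
                return 1, f"E: unable to fetch {name}"
            fname, content = self.registry.artifact(name, eco, version)
            session["files"][fname] = content
            session["log"].append(f"fetched {eco}:{name}=={version} -> {fname}")
            return 0, session["log"][-1]
        return 0, f"ran: {command}"

    def collect_files(self, session: dict, path: str) -> dict[str, bytes]:
        return dict(session["files"])

    def destroy(self, session: dict) -> None:
        self.live_sessions -= 1
        session["files"] = {}
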