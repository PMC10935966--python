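"""Configuration file formats.

Three plain-text formats are understood:

* **package lists** — package names separated by commas and/or newlines,
  one file per ecosystem (``bwa,samtools``);
* **inputconfig.txt** — the per-layer parameter DSL.  Each line declares one
  parameter passed positionally to the layer's ``runMe.sh``::

      Temp Docker:H+R
      Result Folder Name:U+empty
      sharedpath:H+/sharedFolder/
      configpath:H+/sharedFolder/configurationFile.txt

  ``H`` hides the parameter from front-ends, ``U`` shows it as an input box,
  ``R`` draws its value at random from the bundled word list, ``empty``
  leaves it blank; any other ``+``-separated token is a literal value;
* **configurationFile.txt** — holds ``hostPath:<dir>``, the directory where
  generated output folders are written.

All files are read as UTF-8; both LF and CRLF line endings are accepted.
Literal values may contain ``/`` and ``.`` but not ``+`` (there is no
escape mechanism).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import PackageRequest
from .errors import ConfigParseError, ForgeError
from .wordlist import WORDS

HIDDEN = "hidden"
USER_VISIBLE = "user-visible"

RANDOM = "random"
EMPTY = "empty"
LITERAL_LIST = "literal-list"


class DuplicatePackageWarning(UserWarning):
    """A package name occurred more than once in a package list."""


@dataclass(frozen=True)
class ParamSpec:
    """One line of an inputconfig file.

    ``literals`` is non-empty only when ``value_source`` is
    ``"literal-list"`` (a flag-only line yields an empty literal list,
    which must then be satisfied by user input at resolution time).
    """

    label: str
    visibility: str  # HIDDEN | USER_VISIBLE
    value_source: str  # RANDOM | EMPTY | LITERAL_LIST
    literals: tuple[str, ...] = ()
    position: int = 0

    def __post_init__(self) -> None:
        if self.visibility not in (HIDDEN, USER_VISIBLE):
            raise ForgeError(f"bad visibility {self.visibility!r}")
        if self.value_source not in (RANDOM, EMPTY, LITERAL_LIST):
            raise ForgeError(f"bad value_source {self.value_source!r}")
        if self.literals and self.value_source != LITERAL_LIST:
            raise ForgeError("literals only allowed with literal-list source")


@dataclass(frozen=True)
class HostConfig:
    """Where generated output folders are stored on the host."""

    host_path: str


def parse_package_list(text: str, ecosystem: str) -> list[PackageRequest]:
    """Split a comma/newline-separated package list into requests.

    Tokens are whitespace-trimmed, empty tokens dropped, order preserved.
    Duplicates collapse to their first occurrence and raise a
    :class:`DuplicatePackageWarning`.  A token with internal whitespace
    (``"sam tools"``) is a parse error naming the line.
    """
    requests: list[PackageRequest] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        for raw in line.split(","):
            token = raw.strip()
            if not token:
                continue
            if any(c.isspace() for c in token):
                raise ConfigParseError(f"package token contains whitespace: {token!r}", lineno)
            if token in seen:
                warnings.warn(
                    f"duplicate package {token!r} (line {lineno}) collapsed to first occurrence",
                    DuplicatePackageWarning,
                    stacklevel=2,
                )
                continue
            seen.add(token)
            source_ref = token if ecosystem == "source-host" else None
            name = token.rsplit("/", 1)[-1] if ecosystem == "source-host" else token
            requests.append(PackageRequest(name=name, ecosystem=ecosystem, source_ref=source_ref))
    return requests


def _parse_param_line(line: str, lineno: int, position: int) -> ParamSpec:
    if ":" not in line:
        raise ConfigParseError(f"missing ':' separator in {line!r}", lineno)
    label, _, rest = line.partition(":")
    label = label.strip()
    if not label:
        raise ConfigParseError("empty parameter label", lineno)
    tokens = [t.strip() for t in rest.split("+")]
    tokens = [t for t in tokens if t]
    visibility: Optional[str] = None
    value_source: Optional[str] = None
    literals: list[str] = []
    for tok in tokens:
        if tok == "H":
            if visibility is not None:
                raise ConfigParseError("both H and U (or repeated flag) on one line", lineno)
            visibility = HIDDEN
        elif tok == "U":
            if visibility is not None:
                raise ConfigParseError("both H and U (or repeated flag) on one line", lineno)
            visibility = USER_VISIBLE
        elif tok == "R":
            if value_source is not None:
                raise ConfigParseError("R combined with another value source", lineno)
            value_source = RANDOM
        elif tok == "empty":
            if value_source is not None:
                raise ConfigParseError("empty combined with another value source", lineno)
            value_source = EMPTY
        else:
            literals.append(tok)
    if visibility is None:
        raise ConfigParseError("no visibility flag (H or U)", lineno)
    if value_source is not None and literals:
        raise ConfigParseError("literal values cannot combine with R/empty", lineno)
    if value_source is None:
        value_source = LITERAL_LIST
    return ParamSpec(
        label=label,
        visibility=visibility,
        value_source=value_source,
        literals=tuple(literals),
        position=position,
    )


def parse_inputconfig(text: str) -> list[ParamSpec]:
    """Parse an ``inputconfig.txt`` into ordered :class:`ParamSpec` rows.

    Blank lines are skipped; positions are contiguous from 0 in file order.
    """
    specs: list[ParamSpec] = []
    position = 0
    for lineno, line in enumerate(text.replace("\r\n", "\n").split("\n"), start=1):
        if not line.strip():
            continue
        specs.append(_parse_param_line(line, lineno, position))
        position += 1
    return specs


def render_inputconfig(specs: Sequence[ParamSpec]) -> str:
    """Render specs back to canonical text (flag first, then value tokens).

    ``parse_inputconfig(render_inputconfig(specs))`` reproduces ``specs``.
    """
    lines: list[str] = []
    for spec in specs:
        flag = "H" if spec.visibility == HIDDEN else "U"
        parts = [flag]
        if spec.value_source == RANDOM:
            parts.append("R")
        elif spec.value_source == EMPTY:
            parts.append("empty")
        else:
            parts.extend(spec.literals)
        lines.append(f"{spec.label}:" + "+".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def resolve_param_values(
    specs: Sequence[ParamSpec],
    user_inputs: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> list[str]:
    """Produce the positional argument vector for a layer's ``runMe.sh``.

    Pure function of ``(specs, user_inputs, seed)``:

    * random parameters draw from :data:`imageforge.wordlist.WORDS` with a
      ``random.Random(seed)`` generator, in position order;
    * empty parameters default to ``""``;
    * literal-list parameters default to their first literal;
    * user input may override any *user-visible* parameter; a key that does
      not match a user-visible label is an error, as is a user-visible
      literal-list parameter with no literals and no supplied value.
    """
    user_inputs = dict(user_inputs or {})
    visible_labels = {s.label for s in specs if s.visibility == USER_VISIBLE}
    for key in user_inputs:
        if key not in visible_labels:
            raise ForgeError(f"input {key!r} does not match any user-visible parameter")
    rng = random.Random(seed)
    values: list[str] = []
    for spec in sorted(specs, key=lambda s: s.position):
        if spec.visibility == USER_VISIBLE and spec.label in user_inputs:
            values.append(user_inputs[spec.label])
        elif spec.value_source == RANDOM:
            values.append(rng.choice(WORDS))
        elif spec.value_source == EMPTY:
            values.append("")
        elif spec.literals:
            values.append(spec.literals[0])
        else:
            raise ForgeError(
                f"parameter {spec.label!r} has no literals and no supplied value"
            )
    return values


def parse_host_config(text: str) -> HostConfig:
    """Extract ``hostPath:<dir>`` from a configurationFile.txt."""
    for line in text.replace("\r\n", "\n").split("\n"):
        stripped = line.strip()
        if stripped.startswith("hostPath:"):
            value = stripped[len("hostPath:"):].strip()
            if not value:
                raise ConfigParseError("hostPath value is empty")
            return HostConfig(host_path=value)
    raise ConfigParseError("no hostPath line found")
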