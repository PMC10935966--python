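# Methods

## The problem

A Dockerfile is a recipe, not a snapshot. A recipe that says
`pip install scanpy` or `apt-get install samtools` builds a different image
every time upstream repositories move: versions drift, links break,
packages disappear. For bioinformatics analyses — whose conclusions can
change with a library version — that makes "we shipped the Dockerfile"
a weak reproducibility claim.

imageforge implements the stronger claim as a two-phase procedure:

1. **Assembly (capture).** Every requested package and its full dependency
   closure is resolved and *downloaded now*, inside a disposable sandbox
   container that is destroyed afterwards. What is kept is a manifest:
   exact versions, SHA-256 checksums of every artifact file, the
   dependency graph, and a topological install order.
2. **Offline build.** From the manifest the generator emits, per layer, a
   self-contained build folder: a Dockerfile, the captured files packed
   into size-bounded archive volumes, an install script that installs
   *only from those files*, and build/run scripts for POSIX and Windows
   hosts. Rebuilding the image at any later date needs the network for
   exactly one thing — pulling the pinned base image.

"Offline closure" is not a convention here but a checkable property:
`scan_offline_closure` parses a Dockerfile and reports every instruction
that matches a network-fetch deny-list (URL schemes, `git clone`,
`curl`/`wget`, package-manager network verbs such as `apt-get install`,
`pip install` without `--no-index`, `conda install` without `--offline`,
`install.packages(...)`, and so on). The first `FROM` line is the single
permitted remote reference. Every Dockerfile this package generates must
pass the scanner with zero violations; generation fails otherwise.

## Layers

A build plan is an ordered selection of numbered layers, each emitting its
own folder named `<number>_<slug>`:

| layer | folder | contents |
|---|---|---|
| 0 | `0_PythonPackages` / `0_RPackages` | one language stack and its captured packages |
| 1 | `1_mergeDocker` | merge of two layer-0 stacks into one image |
| 2 | `2_GUI_<choice>` | one web IDE (jupyterlab, jupyternotebook, rstudio, visualstudio) on container port 8888 |
| 3 | `3_VMInDocker` | nested docker or singularity runtime |
| 4 | `4_ExternalSoftware` | OS packages (apt ecosystem) |

Two validation modes exist. **Strict** (the default, matching the
front-end semantics): selecting layer N requires every layer below N.
**Permissive** (engine semantics): any subset, e.g. layers {0,1} alone.
Strict-mode validity is monotone — removing the top layer of a valid plan
keeps it valid.

Layers ≥ 2 build `FROM` the previous layer's image tag
(`<image>:layer<N-1>`) rather than repeating its instructions, making the
lineage explicit. Layer 1 is the exception: it builds from the shared
base image and installs both merged package sets, because its inputs are
two *sibling* layer-0 stacks, not a chain. Merging requires both stacks
to be captured against the same base image digest; anything else is
refused rather than silently rebased. Merged volumes keep their two
source streams, renamed with `s0_`/`s1_` prefixes, so filenames cannot
collide and each stream's checksums stay valid.

Image names must be non-empty, at most 128 characters, and lowercase
ASCII letters only — the strictest reading of "lowercase, no numbers or
special characters", so hyphens and underscores are rejected. The
128-character cap is this package's choice (container registries accept
longer names; nothing sensible needs one).

## Dependency capture

Resolution works against an abstract registry catalog
(`versions / dependencies / artifact` per package). Version selection is
the exact pin when one was requested, otherwise the highest available
version under natural ordering (numeric runs compare as integers, so
10.1 > 2.0). The install order is produced by Kahn's algorithm with a
min-heap keyed on `(ecosystem, name)`, which yields the unique
lexicographically smallest topological order — deterministic across runs
and platforms. Cycles are reported with the offending package list.
Tests compare this order against brute-force enumeration of all
topological orders on seeded DAG families (≤ 6 nodes, where enumeration
is exact).

The sandbox backend contract is four operations
(`start / run / collect_files / destroy`); `destroy` is called in a
`finally`, so no sandbox outlives a capture, successful or not — a
counting mock backend asserts exactly this. The shipped engine backend
drives a real `docker` CLI and exists for interactive use only; all
testing runs against the mock.

The generated install script installs strictly in resolved order, one
ecosystem-appropriate offline command per package
(`pip install --no-index --no-deps`, `R CMD INSTALL`, `dpkg -i`,
`conda install --offline`, source-tree unpack), each wrapped in a
marker-file guard so re-running the script is a no-op. Conda/bioconda
requests additionally create their environment under
`/snowflakes/<name>`, the fixed root that makes
`source /snowflakes/<name>/bin/activate` location-independent.
Interpreters themselves are treated as packages of their stack; this
package does not execute source builds.

## Archive chunking

All captured files are serialized into **one deterministic tar+gzip
stream**: entries sorted by path, mtimes zeroed, uid/gid zeroed, mode
normalized to 0644, USTAR format, gzip level 6 with a zeroed timestamp.
The stream is then byte-split into volumes of exactly `limit` bytes
(except the last), named `<stem>.part0000`, `…0001`, …  Byte-splitting a
single stream — rather than bin-packing whole files — means a single file
larger than the limit is handled with no special case, and the volume
count is exactly `ceil(stream_bytes / limit)`.

The default limit is 24 × 10⁶ bytes, strictly below 25 MB under both the
decimal (25 × 10⁶) and binary (25 × 2²⁰) readings of the common
repository-hosting bound, so volumes upload either way. The limit is
configurable per call (`--limit-bytes` on the CLI).

Reassembly verifies each volume's SHA-256 and the whole-stream digest
*before* extracting anything; a missing or corrupted volume is named in
the error and nothing is written. Determinism of the stream means
volumes are diff-stable under version control: re-capturing identical
inputs produces byte-identical volumes.

## Parameter DSL

Each layer folder carries an `inputconfig.txt` whose lines declare the
positional parameters of that layer's `runMe.sh`:
`label:FLAG(+token)*` with `H` (hidden) or `U` (user-visible) mandatory
and first, then either `R` (random), `empty`, or literal values joined by
`+`. Literals may contain `/` and `.` but not `+` (no escape mechanism —
a documented limitation). Random values draw from the bundled 100-word
list in `wordlist.py` with a `random.Random(seed)` generator; the word
list is versioned with the package because changing it changes captured
parameter vectors. A user may override any user-visible parameter;
overriding a hidden one is an error. Parse∘render is the identity on
valid spec lists (property-tested).

## What the fixtures emulate — and what they do not

`fixtures` generates mock registries (seeded DAGs with versioned packages
and artifact stores), synthetic files of exact sizes, and a mock sandbox
backend. Artifacts are seeded pseudorandom bytes behind a
`PKG <name> <version>` header, so install scripts can be order-checked
without any real package manager. Everything is a pure function of
(spec, seed).

What passing these tests shows: the resolution, ordering, chunking,
emission and validation logic is correct against the declared catalog
semantics, and the emitted folders are offline-closed and deterministic.
What it does not show: behavior of real resolvers (backtracking pins,
virtual packages, post-install hooks), real archive layouts of wheels or
`.deb` files, or that the generated images actually build — no container
engine runs in the test environment, and GUI provisioning steps are
template stages whose runtime behavior is untested.

## Numerical and degenerate-input choices

* Empty file sets chunk to an empty ChunkSet (zero volumes), not an error;
  empty request lists capture to an empty manifest with a no-op script.
* Zero-byte files, and single files larger than the volume limit, are
  ordinary inputs (covered by tests at 0 B and 60 MiB).
* Duplicate package names in a config collapse to first occurrence with a
  warning; duplicate paths in a chunk request are an error (silent
  overwrite would corrupt the stream).
* Manifest and chunkset JSON use sorted keys and LF endings; the capture
  timestamp is stored but excluded from canonical serialization, so
  manifests are bit-reproducible.
* Problem sizes in the test and acceptance runs: registries of 2–10
  packages, 50 randomized plans for the closure scan, 30 seeded DAGs for
  the order oracle, file sets to 60 MiB for round-trips — sizes at which
  the brute-force oracles are exact and the full suite stays desk-scale.

## Known limitations

* The deny-list scanner is syntactic; a sufficiently creative Dockerfile
  (e.g. network access from an interpreted heredoc) could evade it. It is
  a guardrail for *generated* output, not a general network linter.
* One conda/bioconda environment per requested package name; sharing an
  environment across requests is not expressed.
* The merge operation is defined for layer-0 pairs only, as in the layer
  model; n-way merges compose pairwise.
* Windows `script.cmd` performs no path translation for the mounted
  shared folder; the mount source is taken as written.
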