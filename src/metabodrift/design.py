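"""Injection-run layouts: conditioning block, periodic pooled QCs, subjects.

A run starts with a block of conditioning QC injections that equilibrate
the column (excluded from all statistics), after which every
``qc_interval``-th injection is a pooled QC; subject samples fill the
remaining positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._utils import ValidationError

ROLE_CONDITIONING = "conditioning_QC"
ROLE_QC = "QC"
ROLE_SUBJECT = "subject"

PLATFORMS = ("GCMS", "UPLC_pos", "UPLC_neg")

#: default number of column-conditioning QC injections at the start of a run
DEFAULT_CONDITIONING = {"GCMS": 5, "UPLC_pos": 10, "UPLC_neg": 10}
#: default subjects per analytical run
DEFAULT_RUN_SUBJECTS = {"GCMS": 30, "UPLC_pos": 60, "UPLC_neg": 60}


@dataclass(frozen=True)
class RunDesign:
    platform: str
    n_subjects: int
    n_conditioning: int
    qc_interval: int
    #: ordered list of (position, role); positions are 1-based and consecutive
    injection_sequence: tuple = field(repr=False)

    @property
    def n_injections(self) -> int:
        return len(self.injection_sequence)

    @property
    def n_qc(self) -> int:
        """Total QC count including the conditioning block."""
        return sum(
            1 for _, r in self.injection_sequence if r in (ROLE_CONDITIONING, ROLE_QC)
        )


def build_run_design(
    platform: str,
    n_subjects: int,
    n_conditioning: int | None = None,
    qc_interval: int = 5,
) -> RunDesign:
    """Lay out one analytical run.

    After the conditioning block, subjects are interleaved so that every
    ``qc_interval``-th post-conditioning injection is a pooled QC, i.e.
    groups of ``qc_interval - 1`` subjects each followed by one QC; a
    trailing incomplete group carries no closing QC.  The interleaved QC
    count is therefore ``n_subjects // (qc_interval - 1)``.
    """
    if platform not in PLATFORMS:
        raise ValidationError(f"unknown platform {platform!r}; expected {PLATFORMS}")
    if n_conditioning is None:
        n_conditioning = DEFAULT_CONDITIONING[platform]
    if n_subjects < 0 or n_conditioning < 0:
        raise ValidationError("counts must be >= 0")
    if qc_interval < 2:
        raise ValidationError(f"qc_interval must be >= 2, got {qc_interval}")

    seq: list[tuple[int, str]] = []
    pos = 1
    for _ in range(n_conditioning):
        seq.append((pos, ROLE_CONDITIONING))
        pos += 1
    placed = 0
    since_qc = 0
    while placed < n_subjects:
        seq.append((pos, ROLE_SUBJECT))
        placed += 1
        pos += 1
        since_qc += 1
        if since_qc == qc_interval - 1 and placed < n_subjects:
            seq.append((pos, ROLE_QC))
            pos += 1
            since_qc = 0
    # closing QC if the final group is complete
    if n_subjects and since_qc == qc_interval - 1:
        seq.append((pos, ROLE_QC))
    return RunDesign(
        platform=platform,
        n_subjects=n_subjects,
        n_conditioning=n_conditioning,
        qc_interval=qc_interval,
        injection_sequence=tuple(seq),
    )


@dataclass(frozen=True)
class BatchDesign:
    batch_id: str
    runs: tuple[RunDesign, ...]

    @property
    def n_subjects(self) -> int:
        return sum(r.n_subjects for r in self.runs)


def build_study_design(
    platform: str,
    n_batches: int = 10,
    subjects_per_batch: int = 120,
    subjects_per_run: int | None = None,
    n_conditioning: int | None = None,
    qc_interval: int = 5,
) -> list[BatchDesign]:
    """Multi-batch study layout (default: 10 batches x 120 subjects).

    Each batch is split into runs of ``subjects_per_run`` subjects
    (platform default: 60 for UPLC, 30 for GC).
    """
    if subjects_per_run is None:
        subjects_per_run = DEFAULT_RUN_SUBJECTS[platform]
    if subjects_per_batch % subjects_per_run:
        raise ValidationError(
            f"subjects_per_batch={subjects_per_batch} not divisible by "
            f"subjects_per_run={subjects_per_run}"
        )
    runs_per_batch = subjects_per_batch // subjects_per_run
    run = build_run_design(platform, subjects_per_run, n_conditioning, qc_interval)
    return [
        BatchDesign(batch_id=f"B{b + 1:02d}", runs=tuple(run for _ in range(runs_per_batch)))
        for b in range(n_batches)
    ]
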