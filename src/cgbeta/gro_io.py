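"""Gromos87 (.gro) reading and writing, and GL-based peptide grouping.

A .gro file holds one or more concatenated blocks (the dialect GROMACS
``trjconv`` emits for multi-frame exports): a title line, an atom count, that
many fixed-column atom lines, and a box line.  Atom lines follow
``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` (residue number, residue name, atom name,
atom number, x, y, z in nm); trailing velocity columns are tolerated and
discarded.  Positions are parsed by fixed columns, never by whitespace.

Peptide membership is not encoded in the format.  It is reconstructed from
the *group length* GL (residues per peptide): residues are enumerated in
order of first appearance — a new residue starts whenever the (residue
number, residue name) pair changes between consecutive atom lines, which is
robust to the 5-digit residue-number wrap — and residue ordinal ``r`` maps to
``peptide_id = r // GL``, ``residue_index = r % GL``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grain",
    "Frame",
    "Trajectory",
    "GroParseError",
    "GroFormatError",
    "GroupingError",
    "read_gro",
    "write_gro",
    "filter_backbone",
]


class GroParseError(ValueError):
    """A fixed-column atom line could not be parsed (names the line number)."""


class GroFormatError(ValueError):
    """Block structure is inconsistent (e.g. atom count vs body length)."""


class GroupingError(ValueError):
    """Total residue count is not an exact multiple of the group length."""


@dataclass(frozen=True)
class Grain:
    """One MARTINI backbone bead.

    ``grain_id`` is the 0-based ordinal of the grain within its frame (order
    of appearance in the file); ``peptide_id``/``residue_index`` come from the
    GL grouping; ``position`` is in nm.
    """

    grain_id: int
    peptide_id: int
    residue_index: int
    residue_name: str
    atom_name: str
    position: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.position, dtype=float)


@dataclass
class Frame:
    """One snapshot: an ordered list of grains plus an orthorhombic box.

    ``box`` holds three edge lengths in nm; all-zero means "no box".
    """

    grains: list[Grain]
    box: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_index: int = 0
    title: str = ""

    def __len__(self) -> int:
        return len(self.grains)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array in nm."""
        if not self.grains:
            return np.zeros((0, 3))
        return np.array([g.position for g in self.grains], dtype=float)

    @property
    def peptide_ids(self) -> np.ndarray:
        return np.array([g.peptide_id for g in self.grains], dtype=int)

    @property
    def n_peptides(self) -> int:
        return len({g.peptide_id for g in self.grains})

    def box_or_none(self) -> tuple[float, float, float] | None:
        """The box if usable for minimum-image wrapping, else None."""
        if all(b > 0 for b in self.box):
            return self.box
        return None


@dataclass
class Trajectory:
    frames: list[Frame]
    group_length: int = 1

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


def _open_text(source) -> tuple[io.TextIOBase, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r"), True
    return source, False


def _parse_atom_line(line: str, lineno: int):
    # fixed columns: resid[0:5] resname[5:10] atomname[10:15] atomnum[15:20]
    # x[20:28] y[28:36] z[36:44]; velocities beyond col 44 ignored
    if len(line.rstrip("\n")) < 44:
        raise GroParseError(f"line {lineno}: atom line shorter than 44 columns")
    try:
        resnum = int(line[0:5])
        resname = line[5:10].strip()
        atomname = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed fixed-column field ({exc})") from exc
    if not resname or not atomname:
        raise GroParseError(f"line {lineno}: empty residue or atom name")
    return resnum, resname, atomname, (x, y, z)


def _group_residues(raw_atoms, group_length: int) -> list[Grain]:
    """Assign peptide/residue ordinals from residue-boundary changes."""
    grains: list[Grain] = []
    residue_ordinal = -1
    prev_key = None
    for gid, (resnum, resname, atomname, pos) in enumerate(raw_atoms):
        key = (resnum, resname)
        if key != prev_key:
            residue_ordinal += 1
            prev_key = key
        grains.append(
            Grain(
                grain_id=gid,
                peptide_id=residue_ordinal // group_length,
                residue_index=residue_ordinal % group_length,
                residue_name=resname,
                atom_name=atomname,
                position=pos,
            )
        )
    n_res = residue_ordinal + 1
    if n_res % group_length != 0:
        raise GroupingError(
            f"{n_res} residues is not a multiple of group length "
            f"{group_length} (remainder {n_res % group_length})"
        )
    return grains


def read_gro(source, group_length: int) -> Trajectory:
    """Read a single- or multi-frame .gro file.

    Parameters
    ----------
    source : path or text stream
    group_length : residues per peptide (GL), >= 1.

    Returns
    -------
    Trajectory with one Frame per concatenated Gromos87 block, in file order.
    """
    if group_length < 1:
        raise ValueError("group_length must be >= 1")
    stream, should_close = _open_text(source)
    try:
        lines = stream.readlines()
    finally:
        if should_close:
            stream.close()
    while lines and lines[-1].strip() == "":
        lines.pop()
    frames: list[Frame] = []
    pos = 0
    while pos < len(lines):
        title = lines[pos]
        pos += 1
        if pos >= len(lines):
            raise GroFormatError("unexpected end of file: missing atom count")
        count_line = lines[pos]
        pos += 1
        try:
            n_atoms = int(count_line.strip())
        except ValueError as exc:
            raise GroFormatError(
                f"line {pos}: expected atom count, got {count_line!r}"
            ) from exc
        raw = []
        for _ in range(n_atoms):
            if pos >= len(lines):
                raise GroFormatError(
                    f"unexpected end of file: block declares {n_atoms} atoms, "
                    f"got {len(raw)}"
                )
            raw.append(_parse_atom_line(lines[pos], pos + 1))
            pos += 1
        if pos >= len(lines):
            raise GroFormatError("unexpected end of file: missing box line")
        box_line = lines[pos]
        pos += 1
        lineno = pos
        fields = box_line.split()
        if len(fields) < 3:
            raise GroFormatError(f"line {lineno}: box line has <3 numbers")
        try:
            box = tuple(float(v) for v in fields[:3])
        except ValueError as exc:
            raise GroFormatError(f"line {lineno}: non-numeric box entry") from exc
        if len(fields) > 3 and any(float(v) != 0.0 for v in fields[3:]):
            warnings.warn(
                "triclinic box components present; only the orthorhombic "
                "edge lengths are used",
                stacklevel=2,
            )
        grains = _group_residues(raw, group_length)
        frames.append(
            Frame(grains=grains, box=box, frame_index=len(frames),
                  title=title.rstrip("\n"))
        )
    if not frames:
        raise GroFormatError("no Gromos87 blocks found in input")
    n0 = len(frames[0])
    for f in frames:
        if len(f) != n0:
            raise GroFormatError(
                f"frame {f.frame_index} has {len(f)} grains, frame 0 has {n0}"
            )
    return Trajectory(frames=frames, group_length=group_length)


def write_gro(frame: Frame, sink) -> None:
    """Write one frame as a Gromos87 block.

    Residue and atom numbers are emitted modulo 100000 (the GROMACS wrap
    convention for the 5-column fields), so arbitrarily large frames stay
    well-formed; re-reading recovers boundaries because consecutive residues
    always differ in the wrapped number.  Coordinates are quantized to
    0.001 nm by the %8.3f fields.
    """
    stream, should_close = (
        (open(sink, "w"), True) if isinstance(sink, (str, Path)) else (sink, False)
    )
    try:
        stream.write((frame.title or "frame") + "\n")
        stream.write(f"{len(frame.grains):5d}\n")
        res_ordinal = 0
        prev = None
        for i, g in enumerate(frame.grains):
            key = (g.peptide_id, g.residue_index)
            if key != prev:
                if prev is not None:
                    res_ordinal += 1
                prev = key
            resnum = (res_ordinal % 100000) + 1
            atomnum = (i % 100000) + 1
            x, y, z = g.position
            stream.write(
                f"{resnum:5d}{g.residue_name:<5s}{g.atom_name:>5s}{atomnum:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        bx, by, bz = frame.box
        stream.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
    finally:
        if should_close:
            stream.close()


def filter_backbone(frame: Frame, atom_name: str = "BB") -> Frame:
    """Keep only grains whose atom name matches, renumbering compactly.

    Peptide and residue assignment are preserved from the original frame (one
    backbone bead per residue means the grouping is unchanged); grain_id
    ordinals are reassigned to stay contiguous.
    """
    kept = [g for g in frame.grains if g.atom_name == atom_name]
    if not kept:
        raise ValueError(
            f"no grains with atom name {atom_name!r}; check the backbone "
            f"atom-name flag against the input file"
        )
    grains = [
        Grain(
            grain_id=i,
            peptide_id=g.peptide_id,
            residue_index=g.residue_index,
            residue_name=g.residue_name,
            atom_name=g.atom_name,
            position=g.position,
        )
        for i, g in enumerate(kept)
    ]
    return Frame(grains=grains, box=frame.box, frame_index=frame.frame_index,
                 title=frame.title)
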