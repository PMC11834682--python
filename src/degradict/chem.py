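"""SMILES and reaction standardisation.

Biodegradation reaction corpora write the same compound in many ways
(protonation state, stereo annotation, atom ordering).  Before a
sequence model can treat string equality as molecule equality, every
compound is pushed through a fixed normalisation pipeline:

1. stereochemistry removal (chirality and double-bond geometry),
2. a set of 17 SMIRKS rewrite rules that fix protonation conventions
   (e.g. carboxylic acids are always written as carboxylates) and
   replace the Coenzyme A moiety with a deprotonated hydroxyl,
3. canonical SMILES generation.

After standardisation two SMILES strings are byte-equal iff the rules
consider the molecules equivalent, so the rest of the package can use
plain string sets for product comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "InvalidSmilesError",
    "RuleApplicationError",
    "StandardizationRule",
    "STANDARDIZATION_RULES",
    "Reaction",
    "SmilesStandardizer",
    "strip_stereochemistry",
    "apply_rules",
    "standardize",
    "standardize_reaction",
    "filter_co2",
    "CO2",
]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class RuleApplicationError(RuntimeError):
    """Raised when a standardisation rule produces an unusable molecule."""


@dataclass(frozen=True)
class StandardizationRule:
    """One SMIRKS rewrite applied during standardisation.

    ``smirks`` is a reaction transform ``reactant-pattern >> product-pattern``.
    Product-side charges are written explicitly (``+0`` where an atom is
    neutralised) because RDKit copies unspecified properties from the
    matched reactant atom; the patterns are otherwise the published
    protonation conventions used by biodegradation databases.
    """

    smirks: str
    description: str

    def __post_init__(self):
        rxn = AllChem.ReactionFromSmarts(self.smirks)
        if rxn is None:  # pragma: no cover - ReactionFromSmarts raises first
            raise ValueError(f"invalid SMIRKS: {self.smirks!r}")
        object.__setattr__(self, "_rxn", rxn)

    @property
    def rxn(self):
        return self._rxn


_COA_SMARTS = (
    "CC(C)(COP(O)(=O)OP(O)(=O)OCC1OC(C(O)C1OP(O)(O)=O)n1cnc2c(N)ncnc12)"
    "C(O)C(=O)NCCC(=O)NCCS[$(*):1]>>[O-][$(*):1]"
)

#: The standardisation rule set, applied in this order.  All rules move or
#: remove hydrogens / adjust formal charges; only the CoA replacement
#: changes the heavy-atom skeleton (it excises the Coenzyme A group).
STANDARDIZATION_RULES: Tuple[StandardizationRule, ...] = (
    StandardizationRule(
        "[H][#8:2]-[#6:3]=[#6:1]>>[#6:1]-[#6:3]=[O:2]",
        "Converting an enol group into a keto group.",
    ),
    StandardizationRule(
        _COA_SMARTS,
        "Replacing Coenzyme A (CoA) group with a deprotonated hydroxyl group.",
    ),
    StandardizationRule(
        "[H][S:1]-[#15:2]=[$([#16]),$([#8]):3]>>[S-:1]-[#15:2]=[$([#16]),$([#8]):3]",
        "Removing a hydrogen atom from a sulfur atom that is double-bonded "
        "to a phosphorus atom and either a sulfur or oxygen atom.",
    ),
    StandardizationRule(
        "[H][#8:1]-[#15:2]>>[#8-:1]-[#15:2]",
        "Removing a hydrogen atom from an oxygen atom bonded to a phosphorus atom.",
    ),
    StandardizationRule(
        "[H][N+:1]([H])([H])[#6:2]>>[H][#7+0:1]([H])-[#6:2]",
        "Removing a hydrogen from a positively charged nitrogen atom that "
        "is bonded to a carbon atom.",
    ),
    StandardizationRule(
        "[H][#8:1][C:2]#[N:3]>>[#8-:1][C:2]#[N:3]",
        "Deprotonating an oxygen atom connecting to a carbon atom which is "
        "triple-bonded to a nitrogen atom.",
    ),
    StandardizationRule(
        "[H][#8:1]-[#6:2]=[O:3]>>[#8-:1]-[#6:2]=[O:3]",
        "Removing a hydrogen from an oxygen atom that is in a carboxylic group.",
    ),
    StandardizationRule(
        "[H][#8:1]-[#7+:2](-[*:3])=[O:4]>>[#8-:1]-[#7+:2](-[*:3])=[O:4]",
        "Deprotonating an oxygen atom that is part of a nitro group.",
    ),
    StandardizationRule(
        "[#6;A:1][#6:2](-[#8-:3])=[#6;A:4]>>[#6:1]-[#6:2](-[#8+0:3][H])=[#6;A:4]",
        "Protonating an oxygen atom in an enolate structure.",
    ),
    StandardizationRule(
        "[H][#8:1]-[$([#15]);!$(P([O-])):2]>>[#8-:1]-[#15:2]",
        "Deprotonating an oxygen atom that is bonded to a phosphorus atom, "
        "except when the phosphorus is bonded to an oxygen atom with a "
        "negative charge.",
    ),
    StandardizationRule(
        "[H][#8:1]-[c:2]1[c:3][c:4][c:5]([c:6][c:7]1-[#7+:8](-[#8-:9])=[O:10])"
        "-[#7+:11](-[#8-:12])=[O:13]"
        ">>[#8-:1]-[c:2]1[c:3][c:4][c:5]([c:6][c:7]1-[#7+:8](-[#8-:9])=[O:10])"
        "-[#7+:11](-[#8-:12])=[O:13]",
        "Deprotonating an oxygen atom connecting to a meta-dinitrobenzene.",
    ),
    StandardizationRule(
        "[H][#8:1][S:2]([#8:3][H])(=[O:4])=[O:5]>>[#8-:1][S:2]([#8-:3])(=[O:4])=[O:5]",
        "Removing hydrogen atoms from two hydroxyl groups in sulfuric acid.",
    ),
    StandardizationRule(
        "[#6:1]-[#8:2][S:3]([#8:4][H])(=[O:5])=[O:6]"
        ">>[#6:1]-[#8:2][S:3]([#8-:4])(=[O:5])=[O:6]",
        "Deprotonating a hydroxyl group in a sulfonic acid structure bonded "
        "to a carbon atom.",
    ),
    StandardizationRule(
        "[H][#8:3][S:2]([#6:1])(=[O:4])=[O:5]>>[#6:1][S:2]([#8-:3])(=[O:4])=[O:5]",
        "Removing a hydrogen atom from an oxygen atom in a sulfoxide "
        "structure, forming a sulfonyl group.",
    ),
    StandardizationRule(
        "[H][#8:1][S:2]([*:3])=[O:4]>>[#8-:1][S:2]([*:3])=[O:4]",
        "Deprotonating an oxygen atom in a sulfinyl group structure.",
    ),
    StandardizationRule(
        "[N+:1]([H])>>[N+0:1]",
        "Removing a hydrogen atom from a positively charged nitrogen atom.",
    ),
    StandardizationRule(
        "[H][#8:1]-[c:2]>>[#8-:1]-[c:2]",
        "Removing a hydrogen atom from an oxygen atom bonded to an aromatic "
        "carbon atom.",
    ),
)

_MAX_RULE_APPLICATIONS = 50
_MAX_PASSES = 20


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise InvalidSmilesError(f"invalid SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"invalid SMILES: {smiles!r}")
    return mol


def strip_stereochemistry(smiles: str) -> str:
    """Return ``smiles`` with all stereo descriptors removed.

    Chirality tags (``@``) and double-bond geometry (``/``, ``\\``) are
    cleared on the parsed molecule, so ring-closure syntax is never
    corrupted; the molecular graph is unchanged.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _apply_rule_exhaustively(mol: Chem.Mol, rule: StandardizationRule) -> Chem.Mol:
    """Apply one rule to an explicit-H molecule until it no longer matches."""
    before = Chem.MolToSmiles(mol)
    for _ in range(_MAX_RULE_APPLICATIONS):
        products = rule.rxn.RunReactants((mol,))
        if not products:
            return mol
        out = products[0][0]
        try:
            out.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(out)
            out = Chem.AddHs(out)
        except Exception as exc:
            raise RuleApplicationError(
                f"rule {rule.description!r} produced an unusable molecule "
                f"from {Chem.MolToSmiles(Chem.RemoveHs(mol))!r}"
            ) from exc
        after = Chem.MolToSmiles(out)
        if after == before:  # matched but nothing changed: converged
            return out
        mol, before = out, after
    raise RuleApplicationError(
        f"rule {rule.description!r} did not reach a fixpoint"
    )


def apply_rules(
    smiles: str,
    rules: Sequence[StandardizationRule] = STANDARDIZATION_RULES,
) -> str:
    """Apply the standardisation rules exhaustively to one molecule.

    Each rule is applied until it stops matching, in list order; the whole
    list is then repeated until a full pass changes nothing, so the result
    is a fixpoint of every rule (this is what makes :func:`standardize`
    idempotent even when one rule creates a match for an earlier one, e.g.
    enolate protonation feeding the enol-to-keto rewrite).
    """
    mol = Chem.AddHs(_mol_from_smiles(smiles))
    for _ in range(_MAX_PASSES):
        before = Chem.MolToSmiles(mol)
        for rule in rules:
            mol = _apply_rule_exhaustively(mol, rule)
        if Chem.MolToSmiles(mol) == before:
            break
    else:  # pragma: no cover - rules have no productive cycles
        raise RuleApplicationError("standardisation rules did not converge")
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


def _standardize_fragment(mol: Chem.Mol) -> str:
    Chem.RemoveStereochemistry(mol)
    smiles = apply_rules(Chem.MolToSmiles(mol))
    return Chem.CanonSmiles(smiles)


def standardize(smiles: str) -> str:
    """Standardise a SMILES string (single molecule or dot-separated set).

    Pipeline: stereo removal, SMIRKS rules, canonicalisation.  Components
    of a multi-compound string are standardised independently and re-joined
    in lexicographic order, so a product *set* has exactly one writing.

    Raises :class:`InvalidSmilesError` for unparseable input; this is the
    validity detector used by decoding and pathway prediction.
    """
    mol = _mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return ".".join(sorted(_standardize_fragment(f) for f in frags))


def is_valid_smiles(smiles: str) -> bool:
    """True iff ``smiles`` survives the full standardisation pipeline."""
    try:
        standardize(smiles)
        return True
    except (InvalidSmilesError, RuleApplicationError):
        return False


#: Standardised SMILES of carbon dioxide.
CO2 = "O=C=O"


@dataclass(frozen=True)
class Reaction:
    """A reaction: reactant compounds and product compounds.

    Compounds are stored as tuples of (ideally standardised) SMILES.
    The serialised form is ``reactants>>products`` with ``.`` separating
    compounds on either side.
    """

    reactants: Tuple[str, ...]
    products: Tuple[str, ...]

    @classmethod
    def from_smiles(cls, reaction_smiles: str) -> "Reaction":
        try:
            lhs, rhs = reaction_smiles.split(">>")
        except ValueError:
            raise InvalidSmilesError(
                f"reaction SMILES needs exactly one '>>': {reaction_smiles!r}"
            ) from None
        return cls(
            reactants=tuple(s for s in lhs.split(".") if s),
            products=tuple(s for s in rhs.split(".") if s),
        )

    def to_smiles(self) -> str:
        return ".".join(self.reactants) + ">>" + ".".join(self.products)

    def standardized(self) -> "Reaction":
        return Reaction(
            reactants=tuple(sorted(standardize(".".join(self.reactants)).split("."))),
            products=tuple(sorted(standardize(".".join(self.products)).split("."))),
        )

    @property
    def reactant_smiles(self) -> str:
        return ".".join(self.reactants)

    @property
    def product_smiles(self) -> str:
        return ".".join(self.products)


def standardize_reaction(reaction_smiles: str) -> Reaction:
    """Parse and standardise one ``reactants>>products`` string."""
    return Reaction.from_smiles(reaction_smiles).standardized()


def filter_co2(reactions: Iterable[Reaction]) -> List[Reaction]:
    """Drop reactions whose *sole* product is carbon dioxide.

    Such entries represent complete mineralisation of the reactant, which
    is over-idealised; reactions producing CO2 alongside other products
    are kept.  Input order is preserved.
    """
    return [r for r in reactions if set(r.products) != {CO2}]


class SmilesStandardizer:
    """Scikit-learn style transformer wrapping :func:`standardize`.

    Parameters
    ----------
    on_invalid : {"raise", "none"}
        ``"raise"`` propagates :class:`InvalidSmilesError`; ``"none"``
        maps unparseable entries to ``None`` (useful when scoring decoded
        model output where invalidity is data, not an error).
    """

    def __init__(self, on_invalid: str = "raise"):
        self.on_invalid = on_invalid

    def get_params(self, deep: bool = True) -> dict:
        return {"on_invalid": self.on_invalid}

    def set_params(self, **params) -> "SmilesStandardizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: Sequence[str], y=None) -> "SmilesStandardizer":
        if self.on_invalid not in ("raise", "none"):
            raise ValueError("on_invalid must be 'raise' or 'none'")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> List[str]:
        self.fit(X)
        out = []
        for smi in X:
            try:
                out.append(standardize(smi))
            except (InvalidSmilesError, RuleApplicationError):
                if self.on_invalid == "raise":
                    raise
                out.append(None)
        return out

    def fit_transform(self, X: Sequence[str], y=None) -> List[str]:
        return self.fit(X).transform(X)
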