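"""Drug feature views computed from SMILES with RDKit.

Two views per drug:

* a 202-dimensional physicochemical-property (PCP) descriptor vector, taken
  from a frozen manifest of RDKit descriptor names so the dimensionality is
  stable across backend releases, and
* the 167-bit MACCS structural-key fingerprint (166 defined keys plus the
  reserved leading bit).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys

from .containers import DrugRecord, FeatureMatrix, FeatureSource
from .errors import ConfigurationError, EmptyDatasetError, FeaturizationError, MifamError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

PCP_DIM = 202
MACCS_DIM = 167

#: Frozen manifest of the 202 physicochemical descriptors, lexicographic by
#: name. The 2-D BCUT family is deliberately excluded: those descriptors
#: depend on partial-charge assignment and are undefined (NaN) for some
#: molecules, which would break the fixed-width contract downstream.
PCP_MANIFEST: tuple[str, ...] = (
    "AvgIpc", "BalabanJ", "BertzCT", "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n",
    "Chi1v", "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v", "EState_VSA1",
    "EState_VSA10", "EState_VSA11", "EState_VSA2", "EState_VSA3", "EState_VSA4",
    "EState_VSA5", "EState_VSA6", "EState_VSA7", "EState_VSA8", "EState_VSA9",
    "ExactMolWt", "FpDensityMorgan1", "FpDensityMorgan2", "FpDensityMorgan3",
    "FractionCSP3", "HallKierAlpha", "HeavyAtomCount", "HeavyAtomMolWt", "Ipc",
    "Kappa1", "Kappa2", "Kappa3", "LabuteASA", "MaxAbsEStateIndex",
    "MaxAbsPartialCharge", "MaxEStateIndex", "MaxPartialCharge",
    "MinAbsEStateIndex", "MinAbsPartialCharge", "MinEStateIndex",
    "MinPartialCharge", "MolLogP", "MolMR", "MolWt", "NHOHCount", "NOCount",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles", "NumAliphaticRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles", "NumAromaticRings",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRadicalElectrons",
    "NumRotatableBonds", "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "NumSaturatedRings", "NumValenceElectrons", "PEOE_VSA1", "PEOE_VSA10",
    "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13", "PEOE_VSA14", "PEOE_VSA2",
    "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5", "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8",
    "PEOE_VSA9", "RingCount", "SMR_VSA1", "SMR_VSA10", "SMR_VSA2", "SMR_VSA3",
    "SMR_VSA4", "SMR_VSA5", "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SPS",
    "SlogP_VSA1", "SlogP_VSA10", "SlogP_VSA11", "SlogP_VSA12", "SlogP_VSA2",
    "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5", "SlogP_VSA6", "SlogP_VSA7",
    "SlogP_VSA8", "SlogP_VSA9", "TPSA", "VSA_EState1", "VSA_EState10",
    "VSA_EState2", "VSA_EState3", "VSA_EState4", "VSA_EState5", "VSA_EState6",
    "VSA_EState7", "VSA_EState8", "VSA_EState9", "fr_Al_COO", "fr_Al_OH",
    "fr_Al_OH_noTert", "fr_ArN", "fr_Ar_COO", "fr_Ar_N", "fr_Ar_NH", "fr_Ar_OH",
    "fr_COO", "fr_COO2", "fr_C_O", "fr_C_O_noCOO", "fr_C_S", "fr_HOCCN",
    "fr_Imine", "fr_NH0", "fr_NH1", "fr_NH2", "fr_N_O", "fr_Ndealkylation1",
    "fr_Ndealkylation2", "fr_Nhpyrrole", "fr_SH", "fr_aldehyde",
    "fr_alkyl_carbamate", "fr_alkyl_halide", "fr_allylic_oxid", "fr_amide",
    "fr_amidine", "fr_aniline", "fr_aryl_methyl", "fr_azide", "fr_azo",
    "fr_barbitur", "fr_benzene", "fr_benzodiazepine", "fr_bicyclic", "fr_diazo",
    "fr_dihydropyridine", "fr_epoxide", "fr_ester", "fr_ether", "fr_furan",
    "fr_guanido", "fr_halogen", "fr_hdrzine", "fr_hdrzone", "fr_imidazole",
    "fr_imide", "fr_isocyan", "fr_isothiocyan", "fr_ketone", "fr_ketone_Topliss",
    "fr_lactam", "fr_lactone", "fr_methoxy", "fr_morpholine", "fr_nitrile",
    "fr_nitro", "fr_nitro_arom", "fr_nitro_arom_nonortho", "fr_nitroso",
    "fr_oxazole", "fr_oxime", "fr_para_hydroxylation", "fr_phenol",
    "fr_phenol_noOrthoHbond", "fr_phos_acid", "fr_phos_ester", "fr_piperdine",
    "fr_piperzine", "fr_priamide", "fr_prisulfonamd", "fr_pyridine", "fr_quatN",
    "fr_sulfide", "fr_sulfonamd", "fr_sulfone", "fr_term_acetylene",
    "fr_tetrazole", "fr_thiazole", "fr_thiocyan", "fr_thiophene",
    "fr_unbrch_alkane", "fr_urea", "qed",
)

assert len(PCP_MANIFEST) == PCP_DIM

_DESCRIPTOR_FNS: dict[str, object] | None = None


def _descriptor_fns() -> dict:
    """Resolve the manifest against the installed backend, once."""
    global _DESCRIPTOR_FNS
    if _DESCRIPTOR_FNS is None:
        available = dict(Descriptors.descList)
        missing = [name for name in PCP_MANIFEST if name not in available]
        if missing:
            raise ConfigurationError(
                "cheminformatics backend is missing descriptors from the "
                f"frozen manifest: {missing}"
            )
        _DESCRIPTOR_FNS = {name: available[name] for name in PCP_MANIFEST}
    return _DESCRIPTOR_FNS


def _parse(record: DrugRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise FeaturizationError(
            f"drug {record.id!r}: SMILES {record.smiles!r} could not be parsed"
        )
    return mol


def compute_pcp(record: DrugRecord) -> np.ndarray:
    """202-dim physicochemical descriptor vector in frozen manifest order.

    Non-finite backend outputs (possible for exotic structures) are replaced
    with 0 and logged, so downstream PCA always receives finite input.
    """
    mol = _parse(record)
    fns = _descriptor_fns()
    values = np.empty(PCP_DIM, dtype=np.float64)
    for i, name in enumerate(PCP_MANIFEST):
        try:
            v = float(fns[name](mol))
        except Exception:  # backend raised on this molecule
            v = math.nan
        if not math.isfinite(v):
            log.warning(
                "drug %s: descriptor %s is non-finite, replaced with 0",
                record.id, name,
            )
            v = 0.0
        values[i] = v
    return values


def compute_maccs(record: DrugRecord) -> np.ndarray:
    """167-bit MACCS key fingerprint as a 0/1 integer vector."""
    mol = _parse(record)
    fp = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(MACCS_DIM, dtype=np.int8)
    bits[list(fp.GetOnBits())] = 1
    return bits


def featurize_drugs(records: list[DrugRecord]) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Compute both drug views for a record list, dropping unparseable records.

    Returns (PCP matrix, MACCS matrix) with identical row-id order.  Rejected
    records are logged with their ids; if every record is rejected an
    :class:`EmptyDatasetError` is raised.
    """
    if not records:
        raise EmptyDatasetError("no drug records supplied")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise MifamError(f"duplicate drug ids: {sorted({i for i in ids if ids.count(i) > 1})}")

    kept_ids: list[str] = []
    pcp_rows: list[np.ndarray] = []
    maccs_rows: list[np.ndarray] = []
    for rec in records:
        try:
            pcp = compute_pcp(rec)
            maccs = compute_maccs(rec)
        except FeaturizationError as exc:
            log.warning("rejected drug record: %s", exc)
            continue
        kept_ids.append(rec.id)
        pcp_rows.append(pcp)
        maccs_rows.append(maccs)
    if not kept_ids:
        raise EmptyDatasetError("all drug records were rejected during featurization")
    return (
        FeatureMatrix(kept_ids, np.vstack(pcp_rows), FeatureSource.PCP,
                      columns=list(PCP_MANIFEST)),
        FeatureMatrix(kept_ids, np.vstack(maccs_rows).astype(np.float64),
                      FeatureSource.MACCS,
                      columns=[f"maccs_{i}" for i in range(MACCS_DIM)]),
    )
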