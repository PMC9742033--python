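import pytest

from pvdili.faers_io import (CaseReport, DemographicRecord, DrugEntry,
                             IndicationEntry, OutcomeEntry, ReactionEntry,
                             TherapyEntry, parse_partial_date)
from pvdili.synthetic_faers import default_config, generate


def make_report(primary_id="1001", case_id=None, case_version=1,
                fda_dt="20200701", event_dt="", age=None, age_unit=None,
                sex=None, occupation=None, country=None,
                drugs=(), reactions=(), outcomes=(), indications=(),
                therapy_starts=()):
    """Assemble a CaseReport from compact tuples.

    drugs: (name, role) or (name, role, start_dt); reactions: PT strings;
    outcomes: codes; indications: terms; therapy_starts: (drug_seq, start_dt).
    """
    case_id = case_id or primary_id
    demo = DemographicRecord(
        primary_id=primary_id, case_id=case_id, case_version=case_version,
        fda_date=parse_partial_date(fda_dt), event_date=parse_partial_date(event_dt),
        age_value=age, age_unit=age_unit, sex=sex,
        reporter_occupation=occupation, reporter_country=country)
    report = CaseReport(demo=demo)
    for seq, spec in enumerate(drugs, start=1):
        name, role, *rest = spec
        start = parse_partial_date(rest[0]) if rest else parse_partial_date("")
        report.drugs.append(DrugEntry(primary_id=primary_id, drug_seq=seq,
                                      drug_name=name, active_ingredient=None,
                                      role_code=role, start_date=start))
    for pt in reactions:
        report.reactions.append(ReactionEntry(primary_id=primary_id, preferred_term=pt))
    for code in outcomes:
        report.outcomes.append(OutcomeEntry(primary_id=primary_id, outcome_code=code))
    for term in indications:
        report.indications.append(IndicationEntry(primary_id=primary_id,
                                                  drug_seq=1, indication_term=term))
    for seq, start in therapy_starts:
        report.therapies.append(TherapyEntry(primary_id=primary_id, drug_seq=seq,
                                             start_date=parse_partial_date(start)))
    return report


@pytest.fixture(scope="session")
def synthetic_quarter(tmp_path_factory):
    """One modest synthetic quarter shared across tests: (dir, config, truth)."""
    outdir = tmp_path_factory.mktemp("quarter")
    config = default_config(n_reports=2000, seed=42, duplicate_rate=0.1)
    _, truth = generate(config, outdir)
    return outdir, config, truth
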