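{
  "description": "Synthetic training vignettes for MTC coding practice. Twelve service descriptions authored for this package, covering 14 distinct gold main-type-of-care codes; three are deliberately incomplete to exercise coding under missing information.",
  "vignettes": [
    {
      "id": "V01",
      "title": "Acute psychiatric ward in a general hospital",
      "text": "A 22-bed ward inside the regional general hospital admitting adults in psychiatric crisis. Physicians are present around the clock; median stay is 12 days.",
      "gold_codes": ["R1.1"],
      "incomplete": false
    },
    {
      "id": "V02",
      "title": "Crisis house run by an NGO",
      "text": "A publicly funded eight-place crisis house outside the hospital campus with nursing staff on site day and night; guests stay up to four weeks.",
      "gold_codes": ["R2.1"],
      "incomplete": false
    },
    {
      "id": "V03",
      "title": "Supported group home with evening visits",
      "text": "A four-person group home for adults with severe mental illness. Support workers visit daily; residents hold indefinite tenancies. The home also runs a weekly activity afternoon.",
      "gold_codes": ["R8.1", "D5.2"],
      "incomplete": false
    },
    {
      "id": "V04",
      "title": "Day hospital",
      "text": "A health-sector day unit offering intensive group programmes five days a week as an alternative to admission; users attend for six to eight weeks.",
      "gold_codes": ["D1.1"],
      "incomplete": false
    },
    {
      "id": "V05",
      "title": "Sheltered workshop",
      "text": "A municipal workshop where adults with psychiatric disability assemble packaging under supervision and receive a stipend. Opening hours and referral route are not recorded.",
      "gold_codes": ["D2.1"],
      "incomplete": true
    },
    {
      "id": "V06",
      "title": "Social club for service users",
      "text": "A drop-in club open three afternoons a week offering coffee, games and peer contact; no structured programme.",
      "gold_codes": ["D5.3"],
      "incomplete": false
    },
    {
      "id": "V07",
      "title": "Assertive community treatment team",
      "text": "A multidisciplinary mobile team (psychiatrist, nurses, social worker) visiting 80 adults with psychosis at home several times a week, with out-of-hours cover.",
      "gold_codes": ["O3.1"],
      "incomplete": false
    },
    {
      "id": "V08",
      "title": "Community mental health centre",
      "text": "The sector outpatient centre providing scheduled appointments with psychiatrists and psychologists; most users are seen at least fortnightly. A duty worker answers information requests from the public.",
      "gold_codes": ["O5.1", "I2"],
      "incomplete": false
    },
    {
      "id": "V09",
      "title": "Psychologist-led counselling service",
      "text": "A clinic offering monthly individual counselling sessions for adults with common mental disorders. Staffing figures were not supplied.",
      "gold_codes": ["O6.1"],
      "incomplete": true
    },
    {
      "id": "V10",
      "title": "Home treatment crisis team",
      "text": "A mobile team responding within 24 hours to psychiatric emergencies at home, available every day of the year.",
      "gold_codes": ["O1.1"],
      "incomplete": false
    },
    {
      "id": "V11",
      "title": "Case coordination office",
      "text": "A two-worker office that arranges and monitors care packages across health and social services for adults with severe mental illness. The target caseload is not stated.",
      "gold_codes": ["A4.1"],
      "incomplete": true
    },
    {
      "id": "V12",
      "title": "Peer-run self-help network",
      "text": "A network of weekly self-help groups facilitated by trained peers in community venues, with a small grant from the health authority.",
      "gold_codes": ["S1"],
      "incomplete": false
    }
  ]
}
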