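{
"label": "What best describes your current stressor?",
"children": [
{
"label": "acute-tension",
"interventions": [
"M001",
"M002",
"M003",
"M004",
"M005",
"M006",
"M007",
"M008",
"M009",
"M010",
"M011",
"M012",
"M013",
"M014",
"M015",
"M016",
"M017",
"M018",
"M019",
"M020",
"M021",
"M022",
"M023",
"M024",
"M025",
"M026",
"M027",
"M028",
"M029",
"M030",
"M031",
"M032",
"M033",
"M034",
"M035",
"M036",
"M037",
"M038",
"M039",
"M040",
"M041",
"M042",
"M043",
"M044",
"M045"
]
},
{
"label": "rumination",
"interventions": [
"M046",
"M047",
"M048",
"M049",
"M050",
"M051",
"M052",
"M053",
"M054",
"M055",
"M056",
"M057",
"M058",
"M059",
"M060",
"M061",
"M062",
"M063",
"M064",
"M065",
"M066",
"M067",
"M068",
"M069",
"M070",
"M071",
"M072",
"M073",
"M074",
"M075",
"M076",
"M077",
"M078",
"M079",
"M080",
"M081",
"M082",
"M083",
"M084",
"M085",
"M086",
"M087",
"M088",
"M089",
"M090"
]
},
{
"label": "overload",
"interventions": [
"M091",
"M092",
"M093",
"M094",
"M095",
"M096",
"M097",
"M098",
"M099",
"M100",
"M101",
"M102",
"M103",
"M104",
"M105",
"M106",
"M107",
"M108",
"M109",
"M110",
"M111",
"M112",
"M113",
"M114",
"M115",
"M116",
"M117",
"M118",
"M119",
"M120",
"M121",
"M122",
"M123",
"M124",
"M125",
"M126",
"M127",
"M128",
"M129",
"M130",
"M131",
"M132",
"M133",
"M134",
"M135"
]
},
{
"label": "interpersonal",
"interventions": [
"M136",
"M137",
"M138",
"M139",
"M140",
"M141",
"M142",
"M143",
"M144",
"M145",
"M146",
"M147",
"M148",
"M149",
"M150",
"M151",
"M152",
"M153",
"M154",
"M155",
"M156",
"M157",
"M158",
"M159",
"M160",
"M161",
"M162",
"M163",
"M164",
"M165",
"M166",
"M167",
"M168",
"M169",
"M170",
"M171",
"M172",
"M173",
"M174",
"M175",
"M176",
"M177",
"M178",
"M179"
]
}
]
}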