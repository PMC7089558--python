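{
  "version": "1.0",
  "variant": "PAT2.0",
  "comment": "PAT 2.0 item register. Ids and labels of the 38 network items follow the published instrument exactly; ids/labels of non-network scored items (6, 9, 10, 11o) and of the optional sibling scale (12a-12o) are package-assigned placeholders.",
  "items": [
    {"id": "1", "label": "mag18", "subscale": "structure_resources", "in_network": true},
    {"id": "2", "label": "educ", "subscale": "structure_resources", "in_network": true},
    {"id": "3", "label": "statciv", "subscale": "structure_resources", "in_network": true},
    {"id": "4a", "label": "childcare", "subscale": "social_support", "in_network": true},
    {"id": "4b", "label": "emotsup", "subscale": "social_support", "in_network": true},
    {"id": "4c", "label": "finsup", "subscale": "social_support", "in_network": true},
    {"id": "4d", "label": "supinf", "subscale": "social_support", "in_network": true},
    {"id": "5", "label": "transport", "subscale": "structure_resources", "in_network": true},
    {"id": "6", "label": "housing", "subscale": "structure_resources", "in_network": false},
    {"id": "7/8", "label": "econdif", "subscale": "structure_resources", "in_network": true},
    {"id": "9", "label": "famimpact", "subscale": "structure_resources", "in_network": false},
    {"id": "10", "label": "otherresource", "subscale": "structure_resources", "in_network": false},
    {"id": "11a", "label": "pchangemood", "subscale": "child_problems", "in_network": true},
    {"id": "11b", "label": "pyounger", "subscale": "child_problems", "in_network": true},
    {"id": "11c", "label": "pupsetmd", "subscale": "child_problems", "in_network": true},
    {"id": "11d", "label": "phyperactivy", "subscale": "child_problems", "in_network": true},
    {"id": "11e", "label": "pattdiff", "subscale": "child_problems", "in_network": true},
    {"id": "11f", "label": "pcry-upset", "subscale": "child_problems", "in_network": true},
    {"id": "11g", "label": "pdistracted", "subscale": "child_problems", "in_network": true},
    {"id": "11h", "label": "pworry", "subscale": "child_problems", "in_network": true},
    {"id": "11i", "label": "plearndif", "subscale": "child_problems", "in_network": true},
    {"id": "11j", "label": "psad", "subscale": "child_problems", "in_network": true},
    {"id": "11l", "label": "pdevdelay", "subscale": "child_problems", "in_network": true},
    {"id": "11m", "label": "pshy", "subscale": "child_problems", "in_network": true},
    {"id": "11n", "label": "ppeerdif", "subscale": "child_problems", "in_network": true},
    {"id": "11o", "label": "peatsleep", "subscale": "child_problems", "in_network": false},
    {"id": "11p", "label": "violence", "subscale": "child_problems", "in_network": true},
    {"id": "12a", "label": "schangemood", "subscale": "sibling_problems", "in_network": false},
    {"id": "12b", "label": "syounger", "subscale": "sibling_problems", "in_network": false},
    {"id": "12c", "label": "supsetmd", "subscale": "sibling_problems", "in_network": false},
    {"id": "12d", "label": "shyperactive", "subscale": "sibling_problems", "in_network": false},
    {"id": "12e", "label": "sattdiff", "subscale": "sibling_problems", "in_network": false},
    {"id": "12f", "label": "scryupset", "subscale": "sibling_problems", "in_network": false},
    {"id": "12g", "label": "sdistracted", "subscale": "sibling_problems", "in_network": false},
    {"id": "12h", "label": "sworry", "subscale": "sibling_problems", "in_network": false},
    {"id": "12i", "label": "slearndif", "subscale": "sibling_problems", "in_network": false},
    {"id": "12j", "label": "ssad", "subscale": "sibling_problems", "in_network": false},
    {"id": "12k", "label": "sdevdelay", "subscale": "sibling_problems", "in_network": false},
    {"id": "12l", "label": "sshy", "subscale": "sibling_problems", "in_network": false},
    {"id": "12m", "label": "speerdif", "subscale": "sibling_problems", "in_network": false},
    {"id": "12n", "label": "sviolence", "subscale": "sibling_problems", "in_network": false},
    {"id": "12o", "label": "sother", "subscale": "sibling_problems", "in_network": false},
    {"id": "13a", "label": "exec worry", "subscale": "family_problems", "in_network": true},
    {"id": "13b", "label": "subabuse", "subscale": "family_problems", "in_network": true},
    {"id": "13c", "label": "saddness-depr", "subscale": "family_problems", "in_network": true},
    {"id": "13d", "label": "attentiondif", "subscale": "family_problems", "in_network": true},
    {"id": "13e", "label": "maritaldif", "subscale": "family_problems", "in_network": true},
    {"id": "13g", "label": "alcoholprob", "subscale": "family_problems", "in_network": true},
    {"id": "13h", "label": "childcustody", "subscale": "family_problems", "in_network": true},
    {"id": "13j", "label": "psychprob", "subscale": "family_problems", "in_network": true},
    {"id": "14a", "label": "nightmares", "subscale": "caregiver_stress", "in_network": true},
    {"id": "14b", "label": "anxiety", "subscale": "caregiver_stress", "in_network": true},
    {"id": "14c", "label": "overly reactive", "subscale": "caregiver_stress", "in_network": true},
    {"id": "15a", "label": "faithmd", "subscale": "family_beliefs", "in_network": true},
    {"id": "15c", "label": "faithfam", "subscale": "family_beliefs", "in_network": true},
    {"id": "15f", "label": "faithtreatment", "subscale": "family_beliefs", "in_network": true},
    {"id": "15h", "label": "faithoutcome", "subscale": "family_beliefs", "in_network": true}
  ]
}
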