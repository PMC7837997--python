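{"$defs":{"CodeSystem":{"enum":["ICD-10-GM","SNOMED CT","free-text"],"title":"CodeSystem","type":"string"},"ConditionCode":{"properties":{"code":{"title":"Code","type":"string"},"code_system":{"$ref":"#/$defs/CodeSystem","default":"free-text"}},"required":["code"],"title":"ConditionCode","type":"object"},"ContactPoint":{"description":"A named person or office reachable for study inquiries.","properties":{"name":{"anyOf":[{"type":"string"},{"type":"null"}],"default":null,"title":"Name"},"query_role":{"anyOf":[{"$ref":"#/$defs/QueryRole"},{"type":"null"}],"default":null},"telecom":{"default":[],"items":{"$ref":"#/$defs/Telecom"},"title":"Telecom","type":"array"}},"title":"ContactPoint","type":"object"},"EligibilityCriteria":{"description":"Demographic inclusion criteria: gender plus an age range in years.","properties":{"gender":{"$ref":"#/$defs/Gender","default":"unknown"},"max_age_years":{"anyOf":[{"minimum":0,"type":"number"},{"type":"null"}],"default":null,"title":"Max Age Years"},"min_age_years":{"anyOf":[{"minimum":0,"type":"number"},{"type":"null"}],"default":null,"title":"Min Age Years"}},"title":"EligibilityCriteria","type":"object"},"Gender":{"enum":["male","female","all","unknown"],"title":"Gender","type":"string"},"IdentifierSource":{"description":"Registry that assigned a trial identifier.","enum":["NCT","DRKS","EUDRACT","UTN","LOCAL"],"title":"IdentifierSource","type":"string"},"Language":{"enum":["de","en"],"title":"Language","type":"string"},"LocalizedText":{"properties":{"language":{"$ref":"#/$defs/Language"},"text":{"title":"Text","type":"string"}},"required":["language","text"],"title":"LocalizedText","type":"object"},"QueryRole":{"enum":["public","scientific"],"title":"QueryRole","type":"string"},"RecruitmentStatus":{"description":"FHIR R4 ResearchStudy.status codes (the full value set).","enum":["active","administratively-completed","approved","closed-to-accrual","closed-to-accrual-and-intervention","completed","disapproved","in-review","temporarily-closed-to-accrual","temporarily-closed-to-accrual-and-intervention","withdrawn"],"title":"RecruitmentStatus","type":"string"},"RelatedLink":{"description":"A further-information URL with its label and display text.","properties":{"display":{"default":"","title":"Display","type":"string"},"label":{"default":"","title":"Label","type":"string"},"url":{"title":"Url","type":"string"}},"required":["url"],"title":"RelatedLink","type":"object"},"SiteInfo":{"description":"One participating site's view of a study.","properties":{"contacts":{"default":[],"items":{"$ref":"#/$defs/ContactPoint"},"title":"Contacts","type":"array"},"display_name":{"default":"","title":"Display Name","type":"string"},"recruitment_status":{"$ref":"#/$defs/RecruitmentStatus","default":"active"},"site_id":{"minLength":1,"title":"Site Id","type":"string"}},"required":["site_id"],"title":"SiteInfo","type":"object"},"Telecom":{"properties":{"kind":{"$ref":"#/$defs/TelecomKind"},"value":{"title":"Value","type":"string"}},"required":["kind","value"],"title":"Telecom","type":"object"},"TelecomKind":{"enum":["email","phone"],"title":"TelecomKind","type":"string"},"TrialIdentifier":{"description":"A (registry, system URI, value) triple identifying a study.\n\nEquality and hashing use the normalized ``(system, value)`` pair only;\n``source`` is derivable from ``system`` and never disambiguates further.","properties":{"source":{"$ref":"#/$defs/IdentifierSource"},"system":{"minLength":1,"title":"System","type":"string"},"value":{"minLength":1,"title":"Value","type":"string"}},"required":["source","system","value"],"title":"TrialIdentifier","type":"object"}},"description":"One site-local study record: the core data set plus provenance.","properties":{"acronym":{"anyOf":[{"type":"string"},{"type":"null"}],"default":null,"title":"Acronym"},"conditions":{"items":{"$ref":"#/$defs/ConditionCode"},"title":"Conditions","type":"array"},"descriptions":{"items":{"$ref":"#/$defs/LocalizedText"},"title":"Descriptions","type":"array"},"eligibility":{"$ref":"#/$defs/EligibilityCriteria"},"exporting_site":{"default":"","title":"Exporting Site","type":"string"},"identifiers":{"items":{"$ref":"#/$defs/TrialIdentifier"},"title":"Identifiers","type":"array"},"keywords":{"items":{"type":"string"},"title":"Keywords","type":"array"},"local_id":{"default":"","title":"Local Id","type":"string"},"overall_status":{"$ref":"#/$defs/RecruitmentStatus","default":"active"},"related_links":{"items":{"$ref":"#/$defs/RelatedLink"},"title":"Related Links","type":"array"},"sites":{"items":{"$ref":"#/$defs/SiteInfo"},"title":"Sites","type":"array"},"titles":{"items":{"$ref":"#/$defs/LocalizedText"},"title":"Titles","type":"array"}},"title":"StudyRecord","type":"object"}
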