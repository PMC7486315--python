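10.0–20.0 cm tall, erect. Stem with sessile glands in central and upper parts; with 3–5 distinct internodes. Cauline leaves linear 20.0 × 2.0 mm. Calyx 12.0–13.0 mm long, campanulate at anthesis and clavate in fruit, glabrous or sparsely pubescent; teeth unequal; shorter ones 1.0–1.5 mm, lanceolate, acuminate; longer ones 2.0–3.5 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 6.0–6.5 mm long, ciliate; limbs 6.0 mm long, bifid to less than half, upper-surface pink, lobes oblong, petal limbs cleft to middle or more, divergent; coronal scales 2.0 mm long, ovate, apex entire. Anthophore ca 5.5 mm long, puberulent. Anthers exserted; filaments glabrous. Styles exserted. First pedicel 1–2 cm in flower, 2–3 cm in fruit, erect or spreading, apex antrorse. Capsule 6.0–8.0 mm, oblong, fragile, opaque. Seeds unknown.
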