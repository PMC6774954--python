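condition,pair_id,role,word,english,frequency,related_to
context,kjeks-mage,referent,kjeks,cookie,20,
context,kjeks-mage,referent,mage,belly,6,
context,banan-har,referent,banan,banana,107,
context,banan-har,referent,hår,hair,47,
context,eple-fot,referent,eple,apple,40,
context,eple-fot,referent,fot,foot,11,
context,brod-bein,referent,brød,bread,26,
context,brod-bein,referent,bein,leg,16,
context,kjeks-mage,related,skje,spoon,6,kjeks
context,kjeks-mage,related,badekar,bathtub,,mage
context,banan-har,related,flaske,bottle,6,banan
context,banan-har,related,tannbørste,toothbrush,8,hår
context,eple-fot,related,kopp,cup,17,eple
context,eple-fot,related,bukse,pants,18,fot
context,brod-bein,related,bord,table,4,brød
context,brod-bein,related,bleie,diaper,34,bein
frequency,hund-briller,referent,hund,dog,52,
frequency,hund-briller,referent,briller,glasses,1,
frequency,katt-nokler,referent,katt,cat,35,
frequency,katt-nokler,referent,nøkler,keys,1,
frequency,bok-jakke,referent,bok,book,107,
frequency,bok-jakke,referent,jakke,jacket,15,
frequency,bil-sofa,referent,bil,car,137,
frequency,bil-sofa,referent,sofa,couch,2,
frequency,hund-briller,related,smokk,pacifier,14,hund
frequency,hund-briller,related,pute,pillow,2,briller
frequency,katt-nokler,related,ball,ball,96,katt
frequency,katt-nokler,related,sol,sun,14,nøkler
frequency,bok-jakke,related,telefon,phone,41,bok
frequency,bok-jakke,related,måne,moon,2,jakke
frequency,bil-sofa,related,vann,water,255,bil
frequency,bil-sofa,related,teppe,carpet,14,sofa
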